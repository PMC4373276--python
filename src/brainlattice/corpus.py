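"""Corpus data model and I/O.

A coordinate-based neuroimaging corpus is three tab-separated tables:

* ``coordinates`` — one row per reported activation peak
  (``study_id, x, y, z, space``), mm in MNI space;
* ``authorship`` — ordered author lists per study
  (``study_id, position, author``), position 1-based;
* ``term_freq`` — per-study frequencies of behavioral terms
  (``study_id, term, frequency``), frequency a fraction in [0, 1].

``study_id`` is an opaque string (PubMed IDs in real corpora, synthetic IDs
in fixtures). Principal investigators (PIs) are operationalized as authors
appearing in the last author position on at least two studies; a
single-author paper counts its sole author as last. Author identity is
exact string match after optional whitespace/case normalization — no name
disambiguation is attempted.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COORDINATES_COLUMNS = ["study_id", "x", "y", "z", "space"]
AUTHORSHIP_COLUMNS = ["study_id", "position", "author"]
TERM_FREQ_COLUMNS = ["study_id", "term", "frequency"]

#: Minimum last-author paper count for PI status.
PI_MIN_PAPERS = 2


class CorpusError(ValueError):
    """Invalid corpus contents."""


class SchemaError(CorpusError):
    """A required column is missing."""


# Talairach -> MNI conversion: inverse of the classic piecewise transform
# (small pitch rotation plus z-sign-dependent axis scaling). Approximate by
# construction; adequate for pooling peaks across spaces at meta-analytic
# smoothing scales.
def _rotation_scale(zoom_z: float) -> np.ndarray:
    theta = 0.05
    rot = np.array(
        [
            [1, 0, 0, 0],
            [0, np.cos(theta), np.sin(theta), 0],
            [0, -np.sin(theta), np.cos(theta), 0],
            [0, 0, 0, 1],
        ]
    )
    scale = np.diag([0.99, 0.97, zoom_z, 1.0])
    return rot @ scale


_UP = _rotation_scale(0.92)  # applies above the AC plane (z >= 0)
_DOWN = _rotation_scale(0.84)


def talairach_to_mni(xyz) -> np.ndarray:
    """Map Talairach coordinates (mm) to approximate MNI coordinates."""
    xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
    ones = np.ones((len(xyz), 1))
    homog = np.hstack([xyz, ones])
    up = homog @ np.linalg.inv(_UP).T
    down = homog @ np.linalg.inv(_DOWN).T
    out = np.where((xyz[:, 2] >= 0)[:, None], up[:, :3], down[:, :3])
    return out


@dataclass
class CorpusTables:
    """The three corpus tables, validated together.

    ``orphan_studies`` flags study_ids that occur in authorship/term_freq
    but have no reported coordinates; they are retained but excluded from
    voxelwise analysis (which is driven by the coordinates table).
    """

    coordinates: pd.DataFrame
    authorship: pd.DataFrame
    term_freq: pd.DataFrame
    orphan_studies: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def studies(self) -> list[str]:
        """Sorted study ids with at least one reported coordinate."""
        return sorted(self.coordinates["study_id"].unique())

    def validate(self) -> None:
        for df, cols, name in (
            (self.coordinates, COORDINATES_COLUMNS, "coordinates"),
            (self.authorship, AUTHORSHIP_COLUMNS, "authorship"),
            (self.term_freq, TERM_FREQ_COLUMNS, "term_freq"),
        ):
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise SchemaError(f"{name} table missing column(s): {missing}")

        coords = self.coordinates
        bad = coords[["x", "y", "z"]].apply(pd.to_numeric, errors="coerce")
        if bad.isna().any().any():
            rows = list(coords.index[bad.isna().any(axis=1)])
            raise CorpusError(f"unparseable coordinates at rows {rows}")

        auth = self.authorship
        dup = auth.duplicated(subset=["study_id", "position"])
        if dup.any():
            pairs = auth.loc[dup, ["study_id", "position"]].to_records(index=False)
            raise CorpusError(f"duplicate (study, position) pairs: {list(pairs)}")
        for sid, grp in auth.groupby("study_id"):
            pos = sorted(grp["position"].astype(int))
            if pos != list(range(1, len(pos) + 1)):
                raise CorpusError(
                    f"study {sid}: author positions {pos} are not contiguous 1..k"
                )

        freq = pd.to_numeric(self.term_freq["frequency"], errors="coerce")
        if freq.isna().any() or (freq < 0).any() or (freq > 1).any():
            raise CorpusError("term frequencies must be fractions in [0, 1]")

        known = set(coords["study_id"])
        orphans = (set(auth["study_id"]) | set(self.term_freq["study_id"])) - known
        if orphans:
            logger.warning(
                "%d study id(s) without coordinates flagged: %s",
                len(orphans),
                sorted(orphans)[:10],
            )
        self.orphan_studies = orphans


@dataclass
class PIRoster:
    """Principal investigators: authors last-listed on >= 2 studies."""

    pis: set[str]
    papers_per_pi: dict[str, int]

    def __post_init__(self) -> None:
        under = {a for a in self.pis if self.papers_per_pi.get(a, 0) < PI_MIN_PAPERS}
        if under:
            raise CorpusError(f"roster members below the 2-paper floor: {under}")


def normalize_name(name: str, casefold: bool = False) -> str:
    """Collapse internal whitespace and strip; optionally casefold."""
    out = re.sub(r"\s+", " ", str(name).strip())
    return out.casefold() if casefold else out


def extract_pis(tables: CorpusTables, min_papers: int = PI_MIN_PAPERS) -> PIRoster:
    """Authors whose last-author (highest position) paper count is >= min_papers.

    Single-author papers count their sole author as last author. Invariant
    to authorship row order.
    """
    auth = tables.authorship
    if len(auth) == 0:
        raise CorpusError("authorship table is empty")
    last_idx = auth.groupby("study_id")["position"].idxmax()
    last_authors = auth.loc[last_idx, "author"]
    counts = last_authors.value_counts()
    pis = {a for a, n in counts.items() if n >= min_papers}
    return PIRoster(pis=pis, papers_per_pi={a: int(counts[a]) for a in pis})


def read_corpus(
    coordinates_path,
    authorship_path,
    term_freq_path,
    talairach: str = "drop",
) -> CorpusTables:
    """Read and validate the three TSV tables.

    Rows whose ``space`` is not MNI are either converted with the
    approximate Talairach affine (``talairach="convert"``) or dropped with a
    logged count (``talairach="drop"``, the default).
    """
    if talairach not in ("drop", "convert"):
        raise ValueError("talairach must be 'drop' or 'convert'")
    coords = _read_tsv(coordinates_path, COORDINATES_COLUMNS, "coordinates")
    auth = _read_tsv(authorship_path, AUTHORSHIP_COLUMNS, "authorship")
    tf = _read_tsv(term_freq_path, TERM_FREQ_COLUMNS, "term_freq")

    for col in ("x", "y", "z"):
        parsed = pd.to_numeric(coords[col], errors="coerce")
        bad = parsed.isna() & coords[col].notna()
        if bad.any():
            # +2: header line plus 1-based numbering
            lines = [int(i) + 2 for i in coords.index[bad]]
            raise CorpusError(
                f"coordinates: unparseable value in column '{col}' at line(s) {lines}"
            )
        coords[col] = parsed.astype(float)

    non_mni = coords["space"].astype(str).str.upper() != "MNI"
    if non_mni.any():
        if talairach == "convert":
            tal = coords.loc[non_mni, ["x", "y", "z"]].to_numpy(dtype=float)
            coords.loc[non_mni, ["x", "y", "z"]] = np.round(talairach_to_mni(tal), 1)
            coords.loc[non_mni, "space"] = "MNI"
            logger.info("converted %d Talairach row(s) to MNI", int(non_mni.sum()))
        else:
            logger.warning("dropped %d non-MNI coordinate row(s)", int(non_mni.sum()))
            coords = coords[~non_mni].reset_index(drop=True)

    auth["position"] = pd.to_numeric(auth["position"], errors="raise").astype(int)
    tf["frequency"] = pd.to_numeric(tf["frequency"], errors="raise").astype(float)
    return CorpusTables(coordinates=coords, authorship=auth, term_freq=tf)


def write_corpus(tables: CorpusTables, outdir) -> dict[str, Path]:
    """Write the three tables as TSV under ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("coordinates", tables.coordinates),
        ("authorship", tables.authorship),
        ("term_freq", tables.term_freq),
    ):
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        paths[name] = path
    return paths


def _read_tsv(path, required: list[str], name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{name} table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table missing column(s): {missing}")
    return df
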