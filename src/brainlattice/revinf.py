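"""Reverse-inference maps: per-voxel 2x2 chi-square association between a
binary study labeling and binary voxel activation.

For a label (a behavioral term being present in a study, or an author being
on the paper), each in-mask voxel yields a 2x2 contingency table over
studies — active/inactive crossed with member/nonmember. A Pearson
chi-square test of independence (df=1, no continuity correction) scores the
dependence; p-values are Benjamini–Hochberg corrected per map at rate ``q``
(default 0.05), and surviving voxels with a *positive* association (the
label preferentially co-occurs with activation) are converted to positive
z-scores; everything else is zeroed. The result indexes how preferentially
activation at each voxel is associated with the presence of the label
relative to its absence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .corpus import CorpusTables, PIRoster
from .volgrid import ActivationMatrix, Grid, write_volume

logger = logging.getLogger(__name__)

#: Default FDR rate.
DEFAULT_Q = 0.05
#: A term is "present" in a study iff its frequency >= this threshold.
DEFAULT_TERM_THRESHOLD = 0.001
#: If any expected cell count falls below this, the voxel's test is voided
#: (p := 1) as unreliable.
MIN_EXPECTED = 1.0

_TINY_P = 1e-300  # keeps the z conversion finite when p underflows


class DegenerateLabelError(ValueError):
    """Label with zero members or zero nonmembers — no 2x2 test possible."""


@dataclass
class StudyLabel:
    """A binary labeling of every study in an activation matrix."""

    label_id: str
    member: np.ndarray  # bool, aligned with ActivationMatrix.studies

    def __post_init__(self) -> None:
        self.member = np.asarray(self.member, dtype=bool)

    @property
    def n_member(self) -> int:
        return int(self.member.sum())


@dataclass
class LabelMap:
    """A masked, FDR-thresholded, z-scored map for one label.

    ``z`` is nonzero exactly where the BH-adjusted p is <= q and the
    association is positive; ``p`` holds the adjusted p-values everywhere.
    """

    label_id: str
    z: np.ndarray
    p: np.ndarray
    n_studies: int
    n_member: int

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if not (np.isfinite(self.z).all() and np.isfinite(self.p).all()):
            raise ValueError(f"map {self.label_id}: non-finite values")


def contingency(voxel_column, member) -> tuple[int, int, int, int]:
    """2x2 counts (a, b, c, d) for one voxel.

    a = active & member, b = active & nonmember,
    c = inactive & member, d = inactive & nonmember.
    """
    active = np.asarray(voxel_column, dtype=bool)
    member = np.asarray(member, dtype=bool)
    if active.shape != member.shape:
        raise ValueError("voxel column and label must have equal length")
    a = int(np.sum(active & member))
    b = int(np.sum(active & ~member))
    c = int(np.sum(~active & member))
    d = int(np.sum(~active & ~member))
    return a, b, c, d


def chi_square(counts) -> tuple[float, float, int]:
    """Pearson chi-square of independence on a 2x2 table.

    Returns ``(statistic, p_value, direction)`` with df=1, no continuity
    correction; direction is the sign of ``a*d - b*c`` (positive means the
    label and activation co-occur more than independence predicts). A zero
    row or column marginal makes the statistic undefined: (0, 1, 0) is
    returned to signal "no test possible".
    """
    a, b, c, d = (float(x) for x in counts)
    n = a + b + c + d
    if n <= 0:
        raise ValueError("contingency table total must be positive")
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    if 0 in (row1, row2, col1, col2):
        return 0.0, 1.0, 0
    delta = a * d - b * c
    stat = n * delta**2 / (row1 * row2 * col1 * col2)
    p = float(stats.chi2.sf(stat, df=1))
    return float(stat), p, int(np.sign(delta))


def fdr_bh(p_values, q: float = DEFAULT_Q) -> np.ndarray:
    """Benjamini–Hochberg keep-vector: True where the hypothesis is rejected
    at FDR rate ``q``."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        return np.zeros(0, dtype=bool)
    keep, _, _, _ = multipletests(p_values, alpha=q, method="fdr_bh")
    return keep


def term_labels(
    tables: CorpusTables,
    studies: list[str],
    threshold: float = DEFAULT_TERM_THRESHOLD,
) -> list[StudyLabel]:
    """One label per term: member studies are those whose term frequency is
    at or above ``threshold``."""
    tf = tables.term_freq
    present = tf[tf["frequency"].astype(float) >= threshold]
    by_term = present.groupby("term")["study_id"].agg(set)
    order = {sid: i for i, sid in enumerate(studies)}
    labels = []
    for term in sorted(by_term.index):
        member = np.zeros(len(studies), dtype=bool)
        for sid in by_term[term]:
            if sid in order:
                member[order[sid]] = True
        labels.append(StudyLabel(label_id=term, member=member))
    return labels


def author_labels(
    tables: CorpusTables,
    studies: list[str],
    roster: PIRoster,
) -> list[StudyLabel]:
    """One label per PI: member studies are those the PI appears on (any
    author position)."""
    auth = tables.authorship
    by_author = auth.groupby("author")["study_id"].agg(set)
    order = {sid: i for i, sid in enumerate(studies)}
    labels = []
    for pi in sorted(roster.pis):
        member = np.zeros(len(studies), dtype=bool)
        for sid in by_author.get(pi, set()):
            if sid in order:
                member[order[sid]] = True
        labels.append(StudyLabel(label_id=pi, member=member))
    return labels


def reverse_inference_map(
    am: ActivationMatrix,
    label: StudyLabel,
    q: float = DEFAULT_Q,
    signed: bool = False,
    min_expected: float = MIN_EXPECTED,
) -> LabelMap:
    """Voxelwise chi-square map for one label, BH-corrected over all in-mask
    voxels, z-scored.

    The two-sided chi-square p of a surviving voxel is mapped to a positive
    normal deviate, ``z = Phi^-1(1 - p/2)``; non-surviving or negatively
    associated voxels are zeroed (with ``signed=True`` negative survivors
    get ``-z`` instead).
    """
    member = np.asarray(label.member, dtype=bool)
    n = am.n_studies
    if member.shape != (n,):
        raise ValueError(
            f"label {label.label_id}: member vector length does not match studies"
        )
    n_member = int(member.sum())
    if n_member == 0 or n_member == n:
        raise DegenerateLabelError(
            f"label {label.label_id} is degenerate "
            f"({n_member} members of {n} studies)"
        )

    act = am.values.astype(np.int64)
    act_tot = act.sum(axis=0)
    a = member.astype(np.int64) @ act
    b = act_tot - a
    c = n_member - a
    d = n - n_member - b

    delta = a * d - b * c
    row1, row2 = act_tot, n - act_tot
    col1, col2 = n_member, n - n_member
    denom = row1 * row2 * col1 * col2
    testable = denom > 0

    stat = np.zeros(am.values.shape[1], dtype=float)
    np.divide(n * delta.astype(float) ** 2, denom, out=stat, where=testable)
    p_raw = np.ones_like(stat)
    p_raw[testable] = stats.chi2.sf(stat[testable], df=1)

    # expected counts under independence; void unreliable cells
    with np.errstate(invalid="ignore"):
        e_min = np.minimum.reduce(
            [row1 * col1, row1 * col2, row2 * col1, row2 * col2]
        ) / float(n)
    voided = testable & (e_min < min_expected)
    if voided.any():
        logger.info(
            "label %s: %d voxel(s) voided (expected count < %g)",
            label.label_id,
            int(voided.sum()),
            min_expected,
        )
        p_raw[voided] = 1.0
        stat[voided] = 0.0

    keep = fdr_bh(p_raw, q)
    _, p_adj, _, _ = multipletests(p_raw, alpha=q, method="fdr_bh")

    direction = np.sign(delta)
    direction[~testable | voided] = 0
    z_mag = stats.norm.isf(np.clip(p_raw, _TINY_P, 1.0) / 2.0)
    if signed:
        z = np.where(keep & (direction != 0), z_mag * direction, 0.0)
    else:
        z = np.where(keep & (direction > 0), z_mag, 0.0)
    return LabelMap(
        label_id=label.label_id, z=z, p=p_adj, n_studies=n, n_member=n_member
    )


def batch_maps(
    am: ActivationMatrix,
    labels: list[StudyLabel],
    q: float = DEFAULT_Q,
    **kwargs,
) -> dict[str, LabelMap]:
    """Map every label, skipping (and logging) degenerate ones."""
    maps: dict[str, LabelMap] = {}
    for label in labels:
        try:
            maps[label.label_id] = reverse_inference_map(am, label, q=q, **kwargs)
        except DegenerateLabelError as exc:
            logger.warning("skipping degenerate label: %s", exc)
    return maps


def write_maps(maps: dict[str, LabelMap], grid: Grid, outdir, kind: str = "label"):
    """Write one NIfTI z-map per label plus a TSV index.

    Index columns: label_id, kind, n_member, n_nonzero_voxels, file.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for label_id in sorted(maps):
        lm = maps[label_id]
        safe = "".join(ch if ch.isalnum() or ch in "-_" else "_" for ch in label_id)
        fname = f"{safe}_z.nii"
        write_volume(lm.z, grid, outdir / fname)
        rows.append(
            {
                "label_id": label_id,
                "kind": kind,
                "n_member": lm.n_member,
                "n_nonzero_voxels": int(np.count_nonzero(lm.z)),
                "file": fname,
            }
        )
    index = pd.DataFrame(rows)
    index.to_csv(outdir / "index.tsv", sep="\t", index=False)
    return index
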