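"""Synthetic corpus generator with planted spatial and social structure.

Emulates a coordinate-based neuroimaging corpus small enough to analyze in
seconds while carrying recoverable signal for every downstream stage. The
planted structure mirrors how real literatures are organized:

* Every PI has an exclusive spatial *focus* (an MNI center plus a radius
  setting the peak spread); a study led by that PI draws a fraction
  ``focus_fraction`` of its peaks from an isotropic Gaussian at the focus
  (sigma = radius/2, truncated to the mask) and the rest uniformly over
  in-mask voxels. Exclusive concentrated territory is what makes the
  author's reverse-inference signal recoverable.
* PIs belong to cohorts (research communities); behavioral terms are
  defined over *sets* of PI foci within a cohort, each spanning a pair of
  labs. A study mentions every term whose focus set intersects the study's
  content foci, at a frequency drawn uniform over ``freq_range``. Term
  maps therefore bridge the cohort's territories, which is what lets
  lattice projection group cohort members even though their author maps
  are spatially disjoint.
* Co-publication pairs are planted explicitly: dedicated joint studies
  co-list the two PIs (the second PI leads). Regular studies carry exactly
  one PI plus junior authors, so PI pair counts equal the planted counts
  by construction.

One seed drives everything; the same spec and seed reproduce the tables
byte for byte. A ground-truth manifest records each label's focus, each
study's content, the cohorts and the pair counts for parameter-recovery
tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus import CorpusTables
from .volgrid import Grid

_MAX_TRUNCATION_TRIES = 200

# centers and offsets are multiples of 8 mm: they coincide with voxel
# centers of the default grids (8/4/2 mm), so each planted focus maps to a
# well-defined voxel rather than a point between voxels
_COHORT_CENTERS = {"A": (-32.0, -16.0, 24.0), "B": (16.0, -48.0, -8.0)}
_FOCUS_OFFSETS = [(0.0, 0.0, 0.0), (24.0, 0.0, 0.0), (0.0, 24.0, 0.0)]
_DEFAULT_RADIUS = 10.0


@dataclass(frozen=True)
class Focus:
    """A spatial focus: MNI center (mm) and a radius setting the peak spread."""

    center: tuple[float, float, float]
    radius: float


def default_foci() -> dict[str, Focus]:
    """Six PI foci in two well-separated cohort regions (~63 mm apart),
    >= 20 mm apart within a cohort so each lab's territory is exclusive."""
    foci: dict[str, Focus] = {}
    for cohort, center in _COHORT_CENTERS.items():
        for i, off in enumerate(_FOCUS_OFFSETS):
            c = tuple(float(a + b) for a, b in zip(center, off))
            foci[f"f{cohort}{i + 1}"] = Focus(center=c, radius=_DEFAULT_RADIUS)
    return foci


def default_pi_focus() -> dict[str, str]:
    """PI -> focus; odd PIs form cohort A, even PIs cohort B."""
    return {
        "PI_1": "fA1",
        "PI_3": "fA2",
        "PI_5": "fA3",
        "PI_2": "fB1",
        "PI_4": "fB2",
        "PI_6": "fB3",
    }


def default_term_foci() -> dict[str, list[str]]:
    """Term -> focus set: each term spans a pair of labs within a cohort.

    Pairwise overlap is what chains a cohort's labs together on the
    lattice; broader terms spanning a whole cohort dilute their per-voxel
    counts below what a chi-square can recover at this corpus size.
    """
    return {
        "term_01": ["fA1", "fA2"],
        "term_02": ["fB1", "fB2"],
        "term_03": ["fA2", "fA3"],
        "term_04": ["fB2", "fB3"],
        "term_05": ["fA1", "fA3"],
        "term_06": ["fB1", "fB3"],
    }


@dataclass
class SynthSpec:
    """Study conditions for a synthetic corpus.

    Defaults define the bundled demo corpus: 48 studies (42 regular,
    seven round-robin per PI, plus 6 planted joint papers), 6 PIs in two
    three-lab cohorts, 6 behavioral terms, 8 peaks per study with 90%
    drawn at the study's foci, and three planted PI pairs with 3, 2 and 1
    joint papers (the last deliberately below the default edge threshold).
    Joint papers draw their peaks from both PIs' foci — collaborative work
    spans both labs' territories.
    Seven studies per lab keeps every expected cell count at an exclusive
    focus voxel at or above the chi-square validity guard (49/48 >= 1), so
    clean planted signal is testable rather than voided.
    """

    n_studies: int = 48
    foci: dict[str, Focus] = field(default_factory=default_foci)
    pi_focus: dict[str, str] = field(default_factory=default_pi_focus)
    term_foci: dict[str, list[str]] = field(default_factory=default_term_foci)
    peaks_per_study: int = 8
    focus_fraction: float = 0.9
    planted_pairs: list[tuple[str, str, int]] = field(
        default_factory=lambda: [
            ("PI_1", "PI_3", 3),
            ("PI_2", "PI_4", 2),
            ("PI_1", "PI_2", 1),
        ]
    )
    n_juniors: int = 8
    freq_range: tuple[float, float] = (0.005, 0.05)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.focus_fraction <= 1:
            raise ValueError("focus_fraction must be in [0, 1]")
        if not self.foci:
            raise ValueError("at least one focus is required")
        for pi, f in self.pi_focus.items():
            if f not in self.foci:
                raise ValueError(f"PI {pi} assigned unknown focus {f}")
        for term, fs in self.term_foci.items():
            unknown = [f for f in fs if f not in self.foci]
            if unknown:
                raise ValueError(f"term {term} references unknown foci {unknown}")
        n_joint = sum(c for _, _, c in self.planted_pairs)
        if n_joint >= self.n_studies:
            raise ValueError("planted joint studies exceed n_studies")
        for a, b, _ in self.planted_pairs:
            for name in (a, b):
                if name not in self.pi_focus:
                    raise ValueError(f"planted pair references unknown PI {name}")

    @property
    def pis(self) -> list[str]:
        return sorted(self.pi_focus)

    @property
    def terms(self) -> list[str]:
        return sorted(self.term_foci)


def generate(spec: SynthSpec, grid: Grid) -> tuple[CorpusTables, dict]:
    """Generate (tables, manifest) for a spec on a grid.

    Raises if any focus center lies outside the mask.
    """
    for name in sorted(spec.foci):
        if not grid.contains_mm(spec.foci[name].center)[0]:
            raise ValueError(f"focus {name} center lies outside the mask")

    rng = np.random.default_rng(spec.seed)
    pis = spec.pis
    juniors = [f"J_{i + 1:02d}" for i in range(spec.n_juniors)]

    # study plan: regular studies round-robin over PIs, then planted joint
    # studies; a study's content foci are its listed PIs' foci
    plan: list[tuple[str, list[str]]] = []  # (leading PI, PI block)
    n_joint = sum(c for _, _, c in spec.planted_pairs)
    for j in range(spec.n_studies - n_joint):
        pi = pis[j % len(pis)]
        plan.append((pi, [pi]))
    for a, b, count in spec.planted_pairs:
        plan.extend((b, [a, b]) for _ in range(count))

    coord_rows, auth_rows, term_rows = [], [], []
    study_pi: dict[str, str] = {}
    study_foci: dict[str, list[str]] = {}
    for s, (lead, pi_block) in enumerate(plan):
        sid = f"S_{s + 1:03d}"
        content = [spec.pi_focus[p] for p in pi_block]
        study_pi[sid] = lead
        study_foci[sid] = content

        n_junior = int(rng.integers(1, 3))
        team = list(rng.choice(juniors, size=n_junior, replace=False)) + pi_block
        for pos, author in enumerate(team, start=1):
            auth_rows.append({"study_id": sid, "position": pos, "author": str(author)})

        for _ in range(spec.peaks_per_study):
            if rng.random() < spec.focus_fraction:
                fname = content[int(rng.integers(len(content)))]
                peak = _truncated_gaussian(rng, spec.foci[fname], grid)
            else:
                peak = grid.voxel_centers[rng.integers(grid.n_voxels)]
            x, y, z = (round(float(v), 1) for v in peak)
            coord_rows.append(
                {"study_id": sid, "x": x, "y": y, "z": z, "space": "MNI"}
            )

        lo, hi = spec.freq_range
        for term in spec.terms:
            if any(f in spec.term_foci[term] for f in content):
                term_rows.append(
                    {
                        "study_id": sid,
                        "term": term,
                        "frequency": round(float(rng.uniform(lo, hi)), 6),
                    }
                )

    tables = CorpusTables(
        coordinates=pd.DataFrame(coord_rows),
        authorship=pd.DataFrame(auth_rows),
        term_freq=pd.DataFrame(term_rows),
    )

    # brute-force PI pair counts over the generated table (equal to the
    # planted counts by construction; recomputed, not assumed)
    pair_counts: dict[str, int] = {}
    for _, grp in tables.authorship.groupby("study_id"):
        for a, b in combinations(sorted(set(grp["author"]) & set(pis)), 2):
            key = f"{a}|{b}"
            pair_counts[key] = pair_counts.get(key, 0) + 1

    # a term's primary focus: the focus in its set with the most content
    # studies (first-listed wins ties)
    focus_load = {f: 0 for f in spec.foci}
    for fs in study_foci.values():
        for f in fs:
            focus_load[f] += 1
    label_focus = {pi: spec.pi_focus[pi] for pi in pis}
    for term in spec.terms:
        label_focus[term] = max(
            spec.term_foci[term], key=lambda f: (focus_load[f], -spec.term_foci[term].index(f))
        )

    # focus name fA1 -> cohort "A"; arbitrary names fall back to themselves
    cohort = {
        f: (f[1] if len(f) >= 2 and f[0] == "f" else f) for f in spec.foci
    }
    manifest = {
        "seed": spec.seed,
        "foci": {
            name: {
                "center": list(spec.foci[name].center),
                "radius": spec.foci[name].radius,
            }
            for name in sorted(spec.foci)
        },
        "pis": pis,
        "pi_focus": dict(spec.pi_focus),
        "pi_cohort": {pi: cohort[f] for pi, f in spec.pi_focus.items()},
        "term_foci": {t: list(fs) for t, fs in spec.term_foci.items()},
        "label_focus": label_focus,
        "study_pi": study_pi,
        "study_foci": study_foci,
        "planted_pairs": [[a, b, c] for a, b, c in spec.planted_pairs],
        "pair_counts": pair_counts,
    }
    return tables, manifest


def _truncated_gaussian(rng: np.random.Generator, focus: Focus, grid: Grid) -> np.ndarray:
    """Isotropic Gaussian at the focus center (sigma = radius/2), truncated
    to the mask by rejection; falls back to the center after many misses."""
    center = np.asarray(focus.center, dtype=float)
    sigma = focus.radius / 2.0
    for _ in range(_MAX_TRUNCATION_TRIES):
        peak = center + rng.normal(0.0, sigma, size=3)
        if grid.contains_mm(peak)[0]:
            return peak
    return center


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True))


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
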