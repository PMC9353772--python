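"""Synthetic class-structured metabolomics datasets with planted MDB families.

The generator emulates the structure a high-accuracy untargeted study hands
to the network workflow:

* a universe of CHNOPS formulas obeying the usual elemental-ratio sanity
  bounds (H/C 0.2-3.1, O/C <= 1.5, N/C <= 1.3, S/C <= 0.8, P/C <= 0.3,
  P/O <= 0.34, at least one C and one H), with neutral masses in 80-1000 Da;
* mass families grown by repeatedly applying MDB composition deltas, so the
  dataset MDiN provably contains the planted edges;
* class-structured presence/absence: features created by a class's
  "enriched" MDB occur preferentially in that class, everything else is a
  core feature occurring everywhere at a common rate — occurrence, not
  intensity, carries the class signal, as in real occurrence-driven data;
* sub-ppm relative mass error applied once per feature (a consensus mass,
  as produced by alignment), log-normal intensities, absence as MISSING.

Everything is reproducible from ``SyntheticConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import AlignedMatrix
from .mdbs import MDB, ElementDelta, default_mdb_table, formula_mass

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_formula_universe",
    "grow_mdb_families",
    "generate_dataset",
]

RATIO_BOUNDS = {
    "H/C": (0.2, 3.1),
    "O/C": (0.0, 1.5),
    "N/C": (0.0, 1.3),
    "S/C": (0.0, 0.8),
    "P/C": (0.0, 0.3),
    "P/O": (0.0, 0.34),
}

Formula = tuple[tuple[str, int], ...]  # canonical: ((el, count), ...) sorted


def _canon(counts: Mapping[str, int]) -> Formula:
    return tuple(sorted((el, c) for el, c in counts.items() if c != 0))


def _ratios_ok(f: Mapping[str, int]) -> bool:
    c = f.get("C", 0)
    if c < 1 or f.get("H", 0) < 1:
        return False
    if any(v < 0 for v in f.values()):
        return False
    lo, hi = RATIO_BOUNDS["H/C"]
    if not lo <= f.get("H", 0) / c <= hi:
        return False
    for el, key in (("O", "O/C"), ("N", "N/C"), ("S", "S/C"), ("P", "P/C")):
        if f.get(el, 0) / c > RATIO_BOUNDS[key][1]:
            return False
    o, p = f.get("O", 0), f.get("P", 0)
    if p > 0 and (o == 0 or p / o > RATIO_BOUNDS["P/O"][1]):
        return False
    return True


def generate_formula_universe(
    n: int, seed: int | None = 0, mass_range: tuple[float, float] = (80.0, 1000.0)
) -> list[dict[str, int]]:
    """Draw ``n`` distinct random CHNOPS formulas satisfying the ratio bounds."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[dict[str, int]] = []
    seen: set[Formula] = set()
    while len(out) < n:
        c = int(rng.integers(4, 45))
        h = int(rng.integers(max(1, int(0.2 * c)), int(3.1 * c) + 1))
        f = {
            "C": c,
            "H": h,
            "O": int(rng.integers(0, int(1.5 * c) + 1)),
            "N": int(rng.binomial(int(1.3 * c), 0.08)),
            "S": int(rng.binomial(2, 0.15)),
            "P": int(rng.binomial(2, 0.1)),
        }
        f = {el: v for el, v in f.items() if v}
        if not _ratios_ok(f):
            continue
        if not mass_range[0] <= formula_mass(f) <= mass_range[1]:
            continue
        key = _canon(f)
        if key in seen:
            continue
        seen.add(key)
        out.append(f)
    return out


def _apply_delta(f: Mapping[str, int], delta: ElementDelta, sign: int) -> dict[str, int]:
    out = dict(f)
    for el, c in delta.counts:
        out[el] = out.get(el, 0) + sign * c
    return {el: v for el, v in out.items() if v != 0}


def grow_mdb_families(
    seeds: Sequence[Mapping[str, int]],
    mdbs: Sequence[MDB],
    depth: int,
    seed: int | None = 0,
    creators: Sequence[MDB] | None = None,
    creator_bias: float = 0.0,
) -> tuple[list[dict[str, int]], list[MDB | None], list[tuple[int, int, str]]]:
    """Grow mass families by random MDB application.

    For each seed formula, ``depth`` growth attempts pick a random family
    member, a random MDB and a random direction; children violating the
    element-count/ratio constraints are rejected. ``creators`` with
    ``creator_bias`` > 0 skews the MDB choice toward a subset (used to
    plant class-enriched transformations densely enough to matter).

    Returns (formulas, creating MDB per formula — None for seeds,
    planted edges as (parent index, child index, mdb label)).
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = np.random.default_rng(seed)
    formulas: list[dict[str, int]] = []
    created_by: list[MDB | None] = []
    index: dict[Formula, int] = {}
    edges: list[tuple[int, int, str]] = []
    for f in seeds:
        key = _canon(f)
        if key not in index:
            index[key] = len(formulas)
            formulas.append(dict(f))
            created_by.append(None)
    for fam_root in list(index.values()):
        members = [fam_root]
        for _ in range(depth):
            parent = int(rng.choice(members))
            if creators and rng.random() < creator_bias:
                mdb = creators[int(rng.integers(len(creators)))]
            else:
                mdb = mdbs[int(rng.integers(len(mdbs)))]
            sign = 1 if rng.random() < 0.5 else -1
            child = _apply_delta(formulas[parent], mdb.delta, sign)
            if not _ratios_ok(child):
                continue
            key = _canon(child)
            if key in index:
                ci = index[key]
            else:
                ci = len(formulas)
                index[key] = ci
                formulas.append(child)
                created_by.append(mdb)
            if ci != parent:
                edges.append((parent, ci, mdb.label))
                members.append(ci)
    return formulas, created_by, edges


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate a small multiclass replicate study: 3 classes of
    triplicates, ~40 seed formulas grown 6 steps each, 0.2 ppm consensus
    mass error (well inside the 1 ppm matching tolerance), log-normal
    intensities on the scale of FT-MS peak heights.
    """

    n_classes: int = 3
    samples_per_class: int = 3
    n_seed_formulas: int = 40
    family_depth: int = 6
    core_presence_prob: float = 0.8
    enriched_presence_prob: float = 0.9
    background_presence_prob: float = 0.1
    enriched_mdb_per_class: tuple[str, ...] = ("CH2", "O", "CO2")
    enriched_growth_bias: float = 0.35
    mass_error_ppm: float = 0.2
    intensity_lognormal: tuple[float, float] = (16.0, 1.0)
    include_glycation: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.core_presence_prob,
            self.enriched_presence_prob,
            self.background_presence_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("presence probabilities must lie in [0, 1]")
        if self.mass_error_ppm < 0:
            raise ValueError("mass_error_ppm must be >= 0")
        if len(self.enriched_mdb_per_class) < self.n_classes:
            raise ValueError("need one enriched MDB per class")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset."""

    formulas: list[dict[str, int]]
    created_by: list[str | None]
    planted_edges: list[tuple[str, str, str]]
    class_labels: pd.Series
    enriched_mdb: dict[str, str]


def generate_dataset(cfg: SyntheticConfig) -> tuple[AlignedMatrix, SyntheticTruth]:
    """Generate an aligned matrix plus its ground truth from ``cfg``."""
    rng = np.random.default_rng(cfg.seed)
    mdbs = default_mdb_table(include_glycation=cfg.include_glycation)
    by_label = {m.label: m for m in mdbs}
    enriched = {
        f"class{i + 1}": cfg.enriched_mdb_per_class[i] for i in range(cfg.n_classes)
    }
    for lbl in enriched.values():
        if lbl not in by_label:
            raise ValueError(f"enriched MDB {lbl!r} is not in the active table")
    seeds = generate_formula_universe(
        cfg.n_seed_formulas, seed=int(rng.integers(2**31 - 1))
    )
    creators = [by_label[l] for l in dict.fromkeys(enriched.values())]
    formulas, created_by, edges = grow_mdb_families(
        seeds, mdbs, cfg.family_depth, seed=int(rng.integers(2**31 - 1)),
        creators=creators, creator_bias=cfg.enriched_growth_bias,
    )
    n_feat = len(formulas)
    fids = [f"F{i + 1:04d}" for i in range(n_feat)]
    exact_mass = np.array([formula_mass(f) for f in formulas])
    # one consensus mass per feature, uniform relative error in +-ppm
    err = rng.uniform(-cfg.mass_error_ppm, cfg.mass_error_ppm, size=n_feat) * 1e-6
    mass = exact_mass * (1.0 + err)

    samples = [
        (f"class{i + 1}", f"class{i + 1}_s{j + 1}")
        for i in range(cfg.n_classes)
        for j in range(cfg.samples_per_class)
    ]
    labels = pd.Series({sid: cls for cls, sid in samples})
    creator_label = [m.label if m is not None else None for m in created_by]

    prob = np.full((n_feat, len(samples)), cfg.core_presence_prob)
    enriched_labels = set(enriched.values())
    for fi, lbl in enumerate(creator_label):
        if lbl in enriched_labels:
            for sj, (cls, _) in enumerate(samples):
                prob[fi, sj] = (
                    cfg.enriched_presence_prob
                    if enriched[cls] == lbl
                    else cfg.background_presence_prob
                )
    for _ in range(100):  # regenerate until every sample has a feature
        present = rng.random(prob.shape) < prob
        empty = ~present.any(axis=0)
        if not empty.any():
            break
    else:
        raise RuntimeError("could not generate a dataset without empty samples")

    mu, sigma = cfg.intensity_lognormal
    inten = rng.lognormal(mean=mu, sigma=sigma, size=prob.shape)
    values = np.where(present, inten, np.nan)
    matrix = AlignedMatrix(
        pd.DataFrame(values, index=fids, columns=[sid for _, sid in samples]),
        pd.Series(mass, index=fids),
        labels,
    )
    truth = SyntheticTruth(
        formulas=formulas,
        created_by=creator_label,
        planted_edges=[(fids[u], fids[v], l) for u, v, l in edges],
        class_labels=labels,
        enriched_mdb=enriched,
    )
    return matrix, truth
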