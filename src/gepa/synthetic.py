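"""Synthetic fixtures with known ground truth.

The generator emulates the structure a multi-lineage differentiation
experiment exhibits: blocks of lineage-enriched genes at controllable
fold-change margins, housekeeping-like near-flat genes, gradient genes,
and isoform tables with planted switches.  It is a test harness, not an
RNA-seq read simulator — no length or GC bias, no count noise model beyond
optional multiplicative log-normal jitter.

Design: every plant is specified on the *classifier-ready* scale (the
values the classifier will see after normalization and pseudocount).  The
raw matrix is then constructed as an exact fixed point of the preprocessing
chain: a ballast gene tops every sample column up to the normalization
target, and random per-sample scale factors distort the raw columns (which
normalization must undo — so every fixture also exercises scale
invariance).  With zero noise, preparing the raw matrix reproduces the
planted values up to float rounding, and classification at the design
threshold recovers every planted category.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from gepa.core import PatternLabel, Threshold
from gepa.expression_io import ExpressionTable, GeneList, IsoformTable
from gepa.preprocess import PreprocessConfig

__all__ = [
    "PlantSpec",
    "generate_matrix",
    "generate_housekeeping_like",
    "generate_positive_like",
    "generate_isoform_table",
    "plant_targets",
    "assemble_raw",
    "expected_exceedance",
]

BALLAST_ID = "ballast_0"

#: Largest max/min ratio the ballast gene may exhibit after assembly; kept
#: below any threshold in common use so the ballast is always Even.
BALLAST_EVEN_BOUND = 1.45


@dataclass(frozen=True)
class PlantSpec:
    """One block of planted genes.

    category
        Target :class:`PatternLabel`.  For enriched plants ``margin`` is the
        fold change at the decision cut; for Gradient plants it is the
        overall max/min ratio (the per-step ratio is margin^(1/(N−1))).
    within_block_spread
        Max ratio inside the enriched and non-enriched value blocks; must
        stay below the design threshold so no cut triggers inside a block.
    noise_cv
        Coefficient of variation of multiplicative log-normal jitter applied
        on the raw scale (0 = exact recovery).
    base
        Classifier-ready scale of the non-enriched block (well above the
        pseudocount so planted ratios survive it).
    """

    category: PatternLabel
    n_genes: int
    margin: float = 4.0
    within_block_spread: float = 1.2
    noise_cv: float = 0.0
    base: float = 50.0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.within_block_spread < 1:
            raise ValueError("within_block_spread must be >= 1")
        if self.margin <= 1:
            raise ValueError("margin must be > 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.base <= 1:
            raise ValueError("base must be > 1")


def _geometric_block(top: float, spread: float, m: int) -> np.ndarray:
    """m values spaced geometrically from ``top`` down to ``top/spread``."""
    if m == 1:
        return np.array([top])
    return top / spread ** (np.arange(m) / (m - 1))


def _plant_vector(
    spec: PlantSpec, sample_ids: Sequence[str], t_design: float, rng: np.random.Generator
) -> np.ndarray:
    n = len(sample_ids)
    lab = spec.category
    if spec.within_block_spread >= t_design:
        raise ValueError(
            f"within_block_spread {spec.within_block_spread} must stay below the "
            f"design threshold {t_design} for a clean plant"
        )
    if lab.kind == "even":
        vals = spec.base * _geometric_block(spec.within_block_spread, spec.within_block_spread, n)
        return rng.permutation(vals)
    if lab.kind == "gradient":
        if spec.margin < t_design:
            raise ValueError(f"gradient plant needs margin >= t_design, got {spec.margin}")
        step = spec.margin ** (1.0 / (n - 1))
        if step >= t_design:
            raise ValueError(
                f"gradient plant infeasible: per-step ratio {step:.3f} >= threshold {t_design} "
                f"(margin too large for {n} samples)"
            )
        return spec.base * step ** (n - 1 - np.arange(n, dtype=float))[rng.permutation(n)]
    # enriched
    members = set(lab.enriched_samples)
    unknown = members - set(sample_ids)
    if unknown:
        raise ValueError(f"plant category names unknown sample(s) {sorted(unknown)}")
    m = len(members)
    if not 1 <= m <= n - 1:
        raise ValueError("enriched plant needs a proper non-empty sample subset")
    if spec.margin < t_design:
        raise ValueError(
            f"enriched plant needs margin >= t_design for recovery, got {spec.margin}"
        )
    spread = spec.within_block_spread
    hi = spec.base * spec.margin * _geometric_block(spread, spread, m)
    lo = spec.base * _geometric_block(1.0, spread, n - m)
    out = np.empty(n)
    hi_idx = [i for i, s in enumerate(sample_ids) if s in members]
    lo_idx = [i for i, s in enumerate(sample_ids) if s not in members]
    out[rng.permutation(hi_idx)] = hi
    out[rng.permutation(lo_idx)] = lo
    return out


def plant_targets(
    specs: Sequence[PlantSpec],
    sample_ids: Sequence[str],
    t_design: float,
    rng: np.random.Generator,
    id_prefix: str = "g",
) -> tuple[pd.DataFrame, dict[str, PatternLabel]]:
    """Build the classifier-ready target matrix for a list of plants."""
    if not specs:
        raise ValueError("no plant specs")
    Threshold(t_design)
    rows: list[np.ndarray] = []
    ids: list[str] = []
    truth: dict[str, PatternLabel] = {}
    counter = 0
    for spec in specs:
        tag = spec.category.canonical().replace("&", ".")
        for _ in range(spec.n_genes):
            w = _plant_vector(spec, sample_ids, t_design, rng)
            if spec.noise_cv > 0:
                sigma = float(np.sqrt(np.log1p(spec.noise_cv**2)))
                w = w * rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=w.size)
                w = np.maximum(w, 1.0 + 1e-9)
            gid = f"{id_prefix}{counter:05d}_{tag}"
            counter += 1
            ids.append(gid)
            rows.append(w)
            truth[gid] = spec.category
    return pd.DataFrame(np.vstack(rows), index=ids, columns=list(sample_ids)), truth


def assemble_raw(
    targets: pd.DataFrame,
    rng: np.random.Generator,
    config: PreprocessConfig = PreprocessConfig(),
    ballast_even_bound: float = BALLAST_EVEN_BOUND,
    distort: bool = True,
) -> pd.DataFrame:
    """Turn classifier-ready targets into a raw matrix fixing the pipeline.

    A ballast row tops each column of (targets − pseudocount) up to the
    normalization target, so preparing the result reproduces the targets
    exactly (up to float rounding); random per-sample scale factors are then
    applied, which normalization removes again.  The ballast row is near-flat
    by construction (its max/min ratio is checked against
    ``ballast_even_bound``), hence always classified Even.
    """
    resid = targets.to_numpy() - config.pseudocount
    if (resid < 0).any():
        raise ValueError("target values must be >= pseudocount")
    colsums = resid.sum(axis=0)
    ballast = config.target_total - colsums
    if (ballast <= 0).any():
        raise ValueError(
            "planted mass exceeds the normalization target; lower base/n_genes "
            "or raise target_total"
        )
    ratio = ballast.max() / ballast.min()
    if ratio > ballast_even_bound:
        raise ValueError(
            f"ballast row would spread {ratio:.3f}-fold (> {ballast_even_bound}); "
            "planted mass is too large or too uneven across samples"
        )
    raw = np.vstack([resid, ballast])
    if distort:
        raw = raw * rng.uniform(0.5, 2.0, size=raw.shape[1])
    return pd.DataFrame(raw, index=list(targets.index) + [BALLAST_ID], columns=targets.columns)


def generate_matrix(
    specs: Sequence[PlantSpec],
    sample_ids: Sequence[str],
    t_design: float = 2.5,
    seed: int = 0,
    config: PreprocessConfig = PreprocessConfig(),
    distort: bool = True,
) -> tuple[ExpressionTable, dict[str, PatternLabel]]:
    """Generate a raw-FPKM-scale matrix with planted categories.

    Returns the raw table and the ground-truth label per gene (including
    the Even ballast row).  With ``noise_cv = 0`` in every spec, running
    :func:`gepa.preprocess.prepare_matrix` followed by classification at
    ``t_design`` recovers every planted category.
    """
    rng = np.random.default_rng(seed)
    targets, truth = plant_targets(specs, sample_ids, t_design, rng)
    raw = assemble_raw(targets, rng, config, distort=distort)
    truth = dict(truth)
    truth[BALLAST_ID] = PatternLabel.even()
    return ExpressionTable(raw, normalized=False), truth


def generate_housekeeping_like(
    n: int,
    spread: float,
    seed: int,
    sample_ids: Sequence[str],
    base: float = 100.0,
) -> tuple[GeneList, pd.DataFrame]:
    """Housekeeping-like negative controls on the classifier-ready scale.

    Each gene is flat at a random per-gene level except for one randomly
    chosen sample boosted by a factor drawn uniformly from [1, spread].
    A gene is therefore classified enriched exactly when its boost reaches
    the threshold, so for spread < T the false-positive rate is 0 and for
    spread straddling T it equals the known exceedance fraction
    ``(spread − T)/(spread − 1)`` in expectation (see
    :func:`expected_exceedance`).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if spread < 1:
        raise ValueError("spread must be >= 1")
    rng = np.random.default_rng(seed)
    nS = len(sample_ids)
    levels = base * rng.uniform(0.5, 2.0, size=n)
    vals = np.tile(levels[:, None], (1, nS))
    bump_sample = rng.integers(0, nS, size=n)
    bump = rng.uniform(1.0, spread, size=n)
    vals[np.arange(n), bump_sample] *= bump
    ids = [f"hk{j:05d}" for j in range(n)]
    targets = pd.DataFrame(vals, index=ids, columns=list(sample_ids))
    return GeneList(tuple(ids), "negative_control"), targets


def expected_exceedance(spread: float, threshold: float) -> float:
    """Expected enriched fraction of housekeeping-like genes at a threshold."""
    if spread <= 1:
        return 0.0
    return max(0.0, min(1.0, (spread - threshold) / (spread - 1.0)))


def generate_positive_like(
    n: int,
    seed: int,
    sample_ids: Sequence[str],
    margin_range: tuple[float, float] = (2.0, 2.5),
    base: float = 80.0,
) -> tuple[GeneList, pd.DataFrame]:
    """Single-lineage marker-like positive controls.

    Each gene is enriched in one random sample with a decision margin drawn
    uniformly from ``margin_range``; the remaining samples are flat.  A gene
    is captured at threshold T exactly when its margin reaches T, so the
    false-negative rate rises with T across a margin-straddling range.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = margin_range
    if not 1 < lo <= hi:
        raise ValueError("margin_range must satisfy 1 < lo <= hi")
    rng = np.random.default_rng(seed)
    nS = len(sample_ids)
    levels = base * rng.uniform(0.5, 2.0, size=n)
    vals = np.tile(levels[:, None], (1, nS))
    top = rng.integers(0, nS, size=n)
    vals[np.arange(n), top] *= rng.uniform(lo, hi, size=n)
    ids = [f"pos{j:05d}" for j in range(n)]
    targets = pd.DataFrame(vals, index=ids, columns=list(sample_ids))
    return GeneList(tuple(ids), "positive_control"), targets


def generate_isoform_table(
    gene_plans: Mapping[str, Sequence[PatternLabel]],
    sample_ids: Sequence[str],
    t_design: float = 2.5,
    seed: int = 0,
    config: PreprocessConfig = PreprocessConfig(),
    margin: float = 4.0,
    n_lowdata: int = 2,
) -> tuple[IsoformTable, dict[str, PatternLabel], dict[str, str]]:
    """Isoform table with planted per-isoform categories.

    ``gene_plans`` maps each gene id to the target category of each of its
    isoforms — e.g. a splicing-switch gene carries one isoform enriched in
    the early states and another enriched in the late ones.  ``n_lowdata``
    extra isoforms with non-usable status ("LOWDATA") and junk FPKM are
    interspersed to exercise the usable-status filtering.

    Returns the long-format table, the truth label per isoform id, and the
    isoform → gene map (the Even ballast isoform belongs to gene
    ``"ballast_gene"``).
    """
    if not gene_plans:
        raise ValueError("empty gene plan")
    rng = np.random.default_rng(seed)
    specs: list[PlantSpec] = []
    iso_ids: list[str] = []
    gene_of: dict[str, str] = {}
    for gene_id, labels in gene_plans.items():
        for j, lab in enumerate(labels):
            iso_id = f"{gene_id}.iso{j + 1}"
            iso_ids.append(iso_id)
            gene_of[iso_id] = gene_id
            specs.append(PlantSpec(lab, 1, margin=margin))
    targets, _ = plant_targets(specs, sample_ids, t_design, rng)
    targets.index = iso_ids
    truth = {iso_id: spec.category for iso_id, spec in zip(iso_ids, specs)}
    raw = assemble_raw(targets, rng, config)
    gene_of[BALLAST_ID] = "ballast_gene"
    truth[BALLAST_ID] = PatternLabel.even()
    records = []
    for iso_id in raw.index:
        for s in sample_ids:
            records.append((iso_id, gene_of[iso_id], s, raw.loc[iso_id, s], "OK"))
    for j in range(n_lowdata):
        host = iso_ids[int(rng.integers(0, len(iso_ids)))]
        s = sample_ids[int(rng.integers(0, len(sample_ids)))]
        low_id = f"{host}.lowdata{j}"
        records.append((low_id, gene_of[host], s, float(rng.uniform(0, 1000)), "LOWDATA"))
        gene_of[low_id] = gene_of[host]
    rows = pd.DataFrame(records, columns=["isoform_id", "gene_id", "sample_id", "fpkm", "status"])
    return IsoformTable(rows), truth, gene_of
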