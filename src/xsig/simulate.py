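"""Synthetic SAGE and cohort data with known ground truth.

Two generators cover the pipeline's two data worlds:

* zebrafish-like SAGE tag-count tables, one per oncogene model, with
  planted up/down-regulated gene sets arranged in a controlled three-model
  Venn design (common core plus exclusive regions). Counts are
  negative-binomial (overdispersed Poisson) around heavy-tailed baseline
  abundances. Real libraries run to tens of millions of tags; the desk
  default of 1e5 preserves the count statistics at test-friendly size and a
  full-scale library size is one config field away.
* human-cohort-like log2-intensity matrices in which each sample carries a
  subset of signature memberships; member samples have their signature
  genes additively shifted by a configured multiple of the gene's baseline
  standard deviation.

Every generator is bit-reproducible under a fixed seed and returns the
generating truth alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionTable
from .sage import SignatureGeneSet

MODELS = ("xmrk", "kras", "Myc")
_REGIONS = (
    ("xmrk",),
    ("kras",),
    ("Myc",),
    ("xmrk", "kras"),
    ("xmrk", "Myc"),
    ("kras", "Myc"),
    ("xmrk", "kras", "Myc"),
)


def venn_design(
    common_up: int,
    common_down: int,
    per_model_totals: Mapping[str, tuple[int, int]],
    pairwise: Mapping[tuple[str, ...], tuple[int, int]] | None = None,
) -> dict[str, dict[tuple[str, ...], int]]:
    """Partition per-model up/down totals into the 7 Venn regions.

    ``per_model_totals`` maps model -> (up_total, down_total). The common
    core gets ``common_up``/``common_down``; pairwise regions default to 0
    unless given; the remainder of each model's total goes to its exclusive
    region. Raises if any total is smaller than the regions it must cover.
    """
    if set(per_model_totals) != set(MODELS):
        raise ValueError(f"per_model_totals must cover exactly {MODELS}")
    pairwise = pairwise or {}
    design: dict[str, dict[tuple[str, ...], int]] = {}
    for direction, common in (("up", common_up), ("down", common_down)):
        regions: dict[tuple[str, ...], int] = {r: 0 for r in _REGIONS}
        regions[("xmrk", "kras", "Myc")] = common
        for pair, sizes in pairwise.items():
            key = tuple(m for m in MODELS if m in pair)
            if len(key) != 2:
                raise ValueError(f"bad pairwise key {pair!r}")
            regions[key] = sizes[0] if direction == "up" else sizes[1]
        for i, model in enumerate(MODELS):
            total = per_model_totals[model][0 if direction == "up" else 1]
            shared = sum(
                regions[r] for r in _REGIONS if model in r and len(r) > 1
            )
            exclusive = total - shared
            if exclusive < 0:
                raise ValueError(
                    f"{model} {direction} total {total} smaller than its "
                    f"shared regions ({shared})"
                )
            regions[(model,)] = exclusive
        design[direction] = regions
    return design


@dataclass
class ZebrafishSimConfig:
    """Study-shaped SAGE simulation parameters.

    The defaults mirror the study design: three control livers per model,
    single tumor samples for the two unreplicated models (xmrk, Myc) and a
    replicated tumor group for kras, planted fold change 8 on the designed
    Venn regions, negative-binomial dispersion 0.2, and library sizes drawn
    uniformly from 10-23 million tags per sample. Sampling goes through a
    gamma-Poisson mixture whose cost is independent of library size, so the
    realistic tag depth is also the fast default; smaller desk-scale
    libraries remain one config field away.
    """

    n_genes: int = 2000
    library_size_range: tuple[int, int] = (10_000_000, 23_000_000)
    n_controls: int = 3
    n_tumors_replicated: int = 3
    replicated_models: tuple[str, ...] = ("kras",)
    design: dict[str, dict[tuple[str, ...], int]] = field(
        default_factory=lambda: venn_design(
            21, 16, {"xmrk": (60, 40), "kras": (60, 40), "Myc": (60, 40)}
        )
    )
    fold_change: float = 8.0
    dispersion: float = 0.2
    planted_tpm_band: tuple[float, float] = (20.0, 1000.0)
    rng_seed: int = 0


@dataclass
class SimTruth:
    """Ground truth emitted with every simulated dataset."""

    zebrafish: pd.DataFrame | None = None  # gene_id, model, direction, fc
    human_membership: pd.DataFrame | None = None  # samples x signatures bool
    signatures: dict[str, tuple[str, ...]] = field(default_factory=dict)


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative-binomial draw via gamma-Poisson mixture; var = m + a m^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _assign_regions(
    rng: np.random.Generator,
    eligible: np.ndarray,
    design: Mapping[str, Mapping[tuple[str, ...], int]],
) -> dict[str, dict[tuple[str, ...], np.ndarray]]:
    total = sum(sum(regions.values()) for regions in design.values())
    if total > len(eligible):
        raise ValueError(
            f"Venn design needs {total} genes but only {len(eligible)} "
            "are eligible for planting"
        )
    pool = rng.permutation(eligible)
    out: dict[str, dict[tuple[str, ...], np.ndarray]] = {}
    start = 0
    for direction, regions in design.items():
        out[direction] = {}
        for region, size in regions.items():
            out[direction][region] = np.sort(pool[start : start + size])
            start += size
    return out


def simulate_sage_counts(
    config: ZebrafishSimConfig = ZebrafishSimConfig(),
) -> tuple[dict[str, ExpressionTable], SimTruth]:
    """Simulate one SAGE count table per oncogene model plus ground truth.

    Baseline abundances are log-normal (heavy-tailed) proportions shared by
    all models; a tumor sample's proportions multiply the planted fold
    change into its model's up regions (and divide it out of the down
    regions) before renormalization; counts are negative-binomial at the
    sampled library size. Effects are planted on genes whose baseline TPM
    falls in ``planted_tpm_band`` — signature genes are expressed (the
    selection criteria include a TPM floor) but not library-dominating, so
    the compositional renormalization stays a small perturbation of the
    unplanted genes.
    """
    rng = np.random.default_rng(config.rng_seed)
    genes = np.array([f"g{i:05d}" for i in range(config.n_genes)], dtype=object)
    baseline = rng.lognormal(mean=0.0, sigma=2.0, size=config.n_genes)
    baseline /= baseline.sum()
    lo, hi = config.planted_tpm_band
    eligible = np.flatnonzero((baseline * 1e6 >= lo) & (baseline * 1e6 <= hi))
    assignment = _assign_regions(rng, eligible, config.design)

    truth_rows = []
    tables: dict[str, ExpressionTable] = {}
    for model in MODELS:
        up_idx = np.concatenate(
            [assignment["up"][r] for r in _REGIONS if model in r]
        ).astype(int)
        down_idx = np.concatenate(
            [assignment["down"][r] for r in _REGIONS if model in r]
        ).astype(int)
        tumor_props = baseline.copy()
        tumor_props[up_idx] *= config.fold_change
        tumor_props[down_idx] /= config.fold_change
        tumor_props /= tumor_props.sum()
        n_tumors = (
            config.n_tumors_replicated
            if model in config.replicated_models
            else 1
        )
        cols = {}
        for t in range(n_tumors):
            lib = rng.integers(*config.library_size_range)
            cols[f"{model}_tumor{t + 1}"] = _nb_counts(
                rng, tumor_props * lib, config.dispersion
            )
        for c in range(config.n_controls):
            lib = rng.integers(*config.library_size_range)
            cols[f"{model}_control{c + 1}"] = _nb_counts(
                rng, baseline * lib, config.dispersion
            )
        tables[model] = ExpressionTable(
            pd.DataFrame(cols, index=genes), "tag_count"
        )
        for direction, idx in (("up", up_idx), ("down", down_idx)):
            for g in idx:
                truth_rows.append((genes[g], model, direction, config.fold_change))
    truth = SimTruth(
        zebrafish=pd.DataFrame(
            truth_rows, columns=["gene_id", "model", "direction", "fc"]
        )
    )
    return tables, truth


@dataclass
class HumanCohortSimConfig:
    """Cohort simulation parameters (log2-intensity microarray emulation).

    Per-gene baselines: mean uniform on [6, 12] log2 units, sd uniform on
    [0.3, 0.8]; per-sample noise is one baseline sd. Each sample joins each
    signature subgroup independently with ``membership_prob`` (memberships
    may overlap, giving the co-correlation structure); members get
    ``effect_size`` baseline-sd units added to that signature's genes.
    """

    n_samples: int = 100
    n_genes: int = 1200
    membership_prob: float = 0.2
    effect_size: float = 3.0
    noise_sd: float = 1.0  # in units of the per-gene baseline sd
    baseline_mean_range: tuple[float, float] = (6.0, 12.0)
    baseline_sd_range: tuple[float, float] = (0.3, 0.8)
    rng_seed: int = 0
    membership: pd.DataFrame | None = None  # explicit samples x signatures bool


def simulate_human_cohort(
    config: HumanCohortSimConfig,
    signatures: Sequence,
) -> tuple[ExpressionTable, SimTruth]:
    """Simulate a cohort expression matrix with planted signature subgroups.

    ``signatures`` are SignatureGeneSet/MappedSignature objects (or
    (name, members) pairs) whose members must lie in the simulated gene
    universe g00000..g<n-1>.
    """
    rng = np.random.default_rng(config.rng_seed)
    genes = np.array([f"g{i:05d}" for i in range(config.n_genes)], dtype=object)
    gene_pos = {g: i for i, g in enumerate(genes)}
    sig_idx: dict[str, np.ndarray] = {}
    for sig in signatures:
        if isinstance(sig, SignatureGeneSet):
            name, members = sig.name, sig.members
        elif hasattr(sig, "human_members"):
            name, members = sig.name, sig.human_members
        else:
            name, members = sig
        unknown = [m for m in members if m not in gene_pos]
        if unknown:
            raise ValueError(f"signature {name!r} has unknown gene(s): {unknown[:3]}")
        sig_idx[name] = np.array([gene_pos[m] for m in members], dtype=int)

    samples = [f"hcc{i + 1:03d}" for i in range(config.n_samples)]
    if config.membership is not None:
        membership = config.membership.astype(bool)
        if list(membership.columns) != list(sig_idx):
            raise ValueError("membership columns must match signature names")
    else:
        membership = pd.DataFrame(
            rng.random((config.n_samples, len(sig_idx))) < config.membership_prob,
            index=samples,
            columns=list(sig_idx),
        )
    mean = rng.uniform(*config.baseline_mean_range, size=config.n_genes)
    sd = rng.uniform(*config.baseline_sd_range, size=config.n_genes)
    x = mean[:, None] + rng.normal(
        scale=config.noise_sd, size=(config.n_genes, config.n_samples)
    ) * sd[:, None]
    for j, sample in enumerate(samples):
        for name, idx in sig_idx.items():
            if membership.loc[sample, name]:
                x[idx, j] += config.effect_size * sd[idx]
    x = np.clip(x, 0.0, None)  # intensities are non-negative
    table = ExpressionTable(pd.DataFrame(x, index=genes, columns=samples), "intensity")
    truth = SimTruth(
        human_membership=membership,
        signatures={n: tuple(genes[i] for i in idx) for n, idx in sig_idx.items()},
    )
    return table, truth


def random_signatures(
    n_genes: int,
    sizes: Mapping[str, int],
    rng_seed: int = 0,
    overlap: int = 0,
) -> list[SignatureGeneSet]:
    """Disjoint (or partially overlapping) signatures over the simulated
    gene universe, for wiring simulations together."""
    rng = np.random.default_rng(rng_seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    pool = list(rng.permutation(genes))
    shared = [pool.pop() for _ in range(overlap)]
    out = []
    for name, size in sizes.items():
        own = [pool.pop() for _ in range(size - overlap)]
        out.append(SignatureGeneSet(name, "human", tuple(shared + own)))
    return out
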