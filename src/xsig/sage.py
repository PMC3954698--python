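"""SAGE tag-count normalization, differential expression and signature selection.

The three oncogene-addicted zebrafish liver tumor models are profiled by
SAGE tag counts. Counts are normalized to TPM (tags per million), tested for
differential expression (one-sample t on per-control log2 ratios for the
unreplicated designs; pooled two-sample t on log2 TPM for the replicated
design), filtered by the selection criteria (FC > 1.5, p < 0.05, TPM > 10 in
tumor or control), and the three models' up/down gene lists are intersected
to find the common core.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import MODELS, load_common_gene_table
from .io import ExpressionTable

DE_COLUMNS = ["gene_id", "fc", "direction", "p_value", "tumor_tpm", "control_tpm"]


@dataclass(frozen=True)
class DeCriteria:
    """Selection thresholds for calling a gene deregulated.

    fc_min
        Fold-change magnitude threshold (selected iff fc > fc_min).
    p_max
        p-value threshold (selected iff p < p_max).
    tpm_min
        Expression floor on max(mean tumor TPM, mean control TPM).
    pseudocount
        Additive constant (TPM) applied to numerator and denominator before
        any ratio or log, bounding fold changes for zero counts.
    """

    fc_min: float = 1.5
    p_max: float = 0.05
    tpm_min: float = 10.0
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if not self.fc_min > 1:
            raise ValueError("fc_min must be > 1")
        if not 0 < self.p_max < 1:
            raise ValueError("p_max must be in (0, 1)")
        if self.tpm_min < 0:
            raise ValueError("tpm_min must be >= 0")
        if not self.pseudocount > 0:
            raise ValueError("pseudocount must be > 0")


@dataclass(frozen=True)
class SignatureGeneSet:
    """Named set of gene identifiers defining one tumor signature."""

    name: str
    species: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"signature {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"signature {self.name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.members)

    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)


def normalize_tpm(counts: ExpressionTable) -> ExpressionTable:
    """Normalize tag counts to tags per million (per-sample scaling).

    tpm[g, s] = count[g, s] / library_size[s] * 1e6, so every sample column
    sums to exactly one million.
    """
    if counts.value_kind != "tag_count":
        raise ValueError("normalize_tpm expects a tag_count table")
    libsize = counts.library_sizes()
    zero = libsize[libsize == 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total counts")
    tpm = counts.data.astype(float) / libsize.to_numpy() * 1e6
    return ExpressionTable(tpm, "tpm")


def _floor_variance(var: np.ndarray, floor: float | None = None) -> np.ndarray:
    """Replace zero per-gene variances by the smallest nonzero variance.

    Keeps the t statistic defined for genes with perfectly consistent
    ratios instead of silently dropping them. ``floor`` overrides the
    data-derived value.
    """
    var = np.asarray(var, dtype=float).copy()
    if floor is None:
        nonzero = var[var > 0]
        floor = float(nonzero.min()) if nonzero.size else 1.0
    var[var == 0] = floor
    return var


def _fc_direction(
    tumor_mean: np.ndarray, control_mean: np.ndarray, pseudocount: float
) -> tuple[np.ndarray, np.ndarray]:
    ratio = (tumor_mean + pseudocount) / (control_mean + pseudocount)
    up = ratio >= 1
    fc = np.where(up, ratio, 1.0 / ratio)
    direction = np.where(up, "up", "down")
    return fc, direction


def _as_de_frame(
    gene_ids: Sequence[str],
    fc: np.ndarray,
    direction: np.ndarray,
    p: np.ndarray,
    tumor_mean: np.ndarray,
    control_mean: np.ndarray,
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "fc": fc,
            "direction": direction,
            "p_value": np.clip(p, 0.0, 1.0),
            "tumor_tpm": tumor_mean,
            "control_tpm": control_mean,
        }
    )


def de_test_unreplicated(
    tpm: ExpressionTable,
    tumor_sample: str,
    control_samples: Sequence[str],
    criteria: DeCriteria = DeCriteria(),
    variance_floor: float | None = None,
) -> pd.DataFrame:
    """One-sample t-test for a single tumor against >= 2 controls.

    For each gene, the per-control log2 ratios
    r_c = log2((tumor + pc) / (control_c + pc)) are tested against mean 0
    with a two-sided one-sample t (df = n_controls - 1). The reported fold
    change is the magnitude ratio of pseudocount-adjusted mean TPMs with a
    separate direction flag.
    """
    if len(control_samples) < 2:
        raise ValueError("one-sample ratio t-test requires >= 2 control samples")
    pc = criteria.pseudocount
    tumor = tpm.data[tumor_sample].to_numpy(dtype=float)
    controls = tpm.data[list(control_samples)].to_numpy(dtype=float)
    ratios = np.log2((tumor[:, None] + pc) / (controls + pc))
    n = ratios.shape[1]
    mean_r = ratios.mean(axis=1)
    var_r = _floor_variance(ratios.var(axis=1, ddof=1), variance_floor)
    t = mean_r / np.sqrt(var_r / n)
    p = 2 * stats.t.sf(np.abs(t), df=n - 1)
    p[mean_r == 0] = 1.0
    control_mean = controls.mean(axis=1)
    fc, direction = _fc_direction(tumor, control_mean, pc)
    return _as_de_frame(tpm.gene_ids, fc, direction, p, tumor, control_mean)


def de_test_replicated(
    tpm: ExpressionTable,
    tumor_samples: Sequence[str],
    control_samples: Sequence[str],
    criteria: DeCriteria = DeCriteria(),
    variance_floor: float | None = None,
    welch: bool = False,
) -> pd.DataFrame:
    """Two-sided Student's t-test between replicated tumor and control groups.

    Operates on log2(TPM + pseudocount); pooled variance by default, Welch
    (heteroscedastic) by flag. Groups of identical values give t = 0 and
    p = 1 by convention.
    """
    if len(tumor_samples) < 2 or len(control_samples) < 2:
        raise ValueError("replicated t-test requires >= 2 samples per group")
    pc = criteria.pseudocount
    a = np.log2(tpm.data[list(tumor_samples)].to_numpy(dtype=float) + pc)
    b = np.log2(tpm.data[list(control_samples)].to_numpy(dtype=float) + pc)
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    if welch:
        va_f = _floor_variance(va, variance_floor)
        vb_f = _floor_variance(vb, variance_floor)
        se2 = va_f / na + vb_f / nb
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / ((va_f / na) ** 2 / (na - 1) + (vb_f / nb) ** 2 / (nb - 1))
    else:
        pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        pooled = _floor_variance(pooled, variance_floor)
        t = (ma - mb) / np.sqrt(pooled * (1 / na + 1 / nb))
        df = np.full_like(t, na + nb - 2)
    p = 2 * stats.t.sf(np.abs(t), df=df)
    p[ma == mb] = 1.0
    tumor_mean = tpm.data[list(tumor_samples)].to_numpy(dtype=float).mean(axis=1)
    control_mean = tpm.data[list(control_samples)].to_numpy(dtype=float).mean(axis=1)
    fc, direction = _fc_direction(tumor_mean, control_mean, pc)
    return _as_de_frame(tpm.gene_ids, fc, direction, p, tumor_mean, control_mean)


def select_deregulated(
    results: pd.DataFrame,
    criteria: DeCriteria = DeCriteria(),
    name: str = "signature",
    species: str = "zebrafish",
) -> tuple[SignatureGeneSet | None, SignatureGeneSet | None]:
    """Apply the selection criteria and split selected genes by direction.

    A gene is selected iff fc > fc_min AND p < p_max AND
    max(tumor TPM, control TPM) > tpm_min. Returns (up, down) signatures;
    a direction with no selected gene yields None.
    """
    expressed = results[["tumor_tpm", "control_tpm"]].max(axis=1) > criteria.tpm_min
    selected = results[
        (results["fc"] > criteria.fc_min)
        & (results["p_value"] < criteria.p_max)
        & expressed
    ]

    def _build(direction: str) -> SignatureGeneSet | None:
        members = tuple(selected.loc[selected["direction"] == direction, "gene_id"])
        if not members:
            return None
        return SignatureGeneSet(f"{name}_{direction}", species, members)

    return _build("up"), _build("down")


@dataclass
class VennCounts:
    """Exact membership counts for the 7 regions of a three-set Venn diagram.

    ``regions`` maps a tuple of model names (the sets a region belongs to,
    in input order) to the genes exclusive to exactly those sets.
    """

    model_names: tuple[str, str, str]
    regions: dict[tuple[str, ...], frozenset[str]] = field(default_factory=dict)

    @property
    def counts(self) -> dict[tuple[str, ...], int]:
        return {k: len(v) for k, v in self.regions.items()}

    @property
    def common(self) -> frozenset[str]:
        return self.regions[self.model_names]

    @property
    def union_size(self) -> int:
        return sum(len(v) for v in self.regions.values())


def venn_regions(sets: Mapping[str, frozenset[str] | set[str]]) -> VennCounts:
    """Partition three sets into their 7 exclusive Venn regions."""
    names = tuple(sets)
    if len(names) != 3:
        raise ValueError("venn_regions expects exactly 3 named sets")
    as_sets = {k: frozenset(v) for k, v in sets.items()}
    regions: dict[tuple[str, ...], frozenset[str]] = {}
    for r in range(1, 4):
        for combo in combinations(names, r):
            inside = frozenset.intersection(*(as_sets[n] for n in combo))
            outside = frozenset.union(
                frozenset(), *(as_sets[n] for n in names if n not in combo)
            )
            regions[combo] = inside - outside
    return VennCounts(names, regions)


@dataclass
class IntersectionResult:
    up: VennCounts
    down: VennCounts

    @property
    def common_up(self) -> frozenset[str]:
        return self.up.common

    @property
    def common_down(self) -> frozenset[str]:
        return self.down.common


def intersect_models(
    up_sets: Mapping[str, SignatureGeneSet | frozenset[str] | set[str]],
    down_sets: Mapping[str, SignatureGeneSet | frozenset[str] | set[str]],
) -> IntersectionResult:
    """Intersect three models' up- and down-regulated gene sets.

    Accepts SignatureGeneSet objects or plain sets per model; returns the
    full Venn region breakdown per direction.
    """

    def _members(v) -> frozenset[str]:
        if isinstance(v, SignatureGeneSet):
            return v.member_set()
        return frozenset(v)

    return IntersectionResult(
        up=venn_regions({k: _members(v) for k, v in up_sets.items()}),
        down=venn_regions({k: _members(v) for k, v in down_sets.items()}),
    )


def intersect_common_table(
    table: pd.DataFrame | None = None, p_max: float = 0.05
) -> IntersectionResult:
    """Run the model intersection on the bundled common-gene table.

    Per model a gene counts as deregulated when its p-value is below
    ``p_max`` with the table's shared direction (the table reports fold
    changes as magnitudes; one model's FC may round below the 1.5 cutoff,
    so significance + direction consistency is the reproducible criterion).
    """
    if table is None:
        table = load_common_gene_table()
    up_sets: dict[str, set[str]] = {}
    down_sets: dict[str, set[str]] = {}
    for model in MODELS:
        sig = table[table[f"{model}_p"] < p_max]
        up_sets[model] = set(sig.index[sig["direction"] == "up"])
        down_sets[model] = set(sig.index[sig["direction"] == "down"])
    return intersect_models(up_sets, down_sets)


def qpcr_log2fc(
    ct_target_transgenic: float,
    ct_reference_transgenic: float,
    ct_target_control: float,
    ct_reference_control: float,
) -> float:
    """log2 fold change from qPCR cycle thresholds via -ddCT.

    -ddCT = -[(CT_target - CT_reference)_transgenic
              - (CT_target - CT_reference)_control].
    """
    cts = (
        ct_target_transgenic,
        ct_reference_transgenic,
        ct_target_control,
        ct_reference_control,
    )
    if not all(np.isfinite(cts)):
        raise ValueError("all CT values must be finite")
    d_tg = ct_target_transgenic - ct_reference_transgenic
    d_ctrl = ct_target_control - ct_reference_control
    return -(d_tg - d_ctrl)
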