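"""Synthetic CITE-seq-like datasets with known ground truth.

The generator emulates the structure this tool is built to interrogate: a
low-dimensional ADT modality (~30 surface proteins) and a high-dimensional
RNA modality (thousands of genes) over shared cells, with planted population
structure, planted differential markers, and two or more annotation schemes
whose disagreement (merges, splits, label noise) is fully controlled.

ADT is simulated directly on the normalized scale (Gaussian noise around a
baseline), because the tool consumes normalized ADT — simulating
post-normalization values is the faithful test target.  A planted ADT shift
of δ between two populations with noise σ therefore yields a true Cohen's d
of exactly δ/σ.  RNA is simulated as negative-binomial counts (gamma–Poisson
mixture) and passed through log-CP10K normalization; planted log-fold shifts
on the NB means are calibrated semi-analytically so the standardized effect
on the *normalized* scale matches a requested Cohen's d.

Two ready-made scenarios cover the acceptance conditions:

* :func:`differential_scenario` — several groups, each with a handful of
  planted upregulated RNA (and ADT) markers at d = 2;
* :func:`isoform_scenario` — two subpopulations identical in RNA but
  separated (d = 2) in two anti-correlated ADT features, with one annotation
  scheme distinguishing them and another merging them (the protein-isoform
  disagreement shape: two cell states the transcriptome cannot tell apart).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import io as aio
from .data_model import ExpressionMatrix, MultimodalDataset
from .errors import ValidationError

logger = logging.getLogger(__name__)


# -- scenario specification ---------------------------------------------------


@dataclass
class AdtParams:
    """Normalized-scale ADT simulation parameters.

    ``shifts`` maps ``(population, feature_name) -> delta`` added to the
    baseline for that population's cells; with noise ``sigma``, a shift of
    ``delta`` relative to an unshifted population is a true Cohen's d of
    ``delta / sigma``.
    """

    n_features: int = 30
    baseline: float = 1.0
    sigma: float = 0.5
    shifts: dict = field(default_factory=dict)
    feature_names: list[str] | None = None

    def resolved_feature_names(self) -> list[str]:
        if self.feature_names is not None:
            return list(self.feature_names)
        return [f"ADT{j + 1:02d}" for j in range(self.n_features)]


@dataclass
class RnaParams:
    """Count-scale RNA simulation parameters.

    Counts are negative binomial with per-feature mean ``mean`` (drawn
    log-normal(log 2, 1) when None — typical droplet magnitudes) and
    dispersion φ (variance m + φ m²).  ``shifts`` maps
    ``(population, feature_name) -> log-fold shift`` applied to the mean.
    """

    n_features: int = 2000
    mean: np.ndarray | None = None
    dispersion: float = 0.5
    shifts: dict = field(default_factory=dict)
    feature_names: list[str] | None = None

    def resolved_feature_names(self) -> list[str]:
        if self.feature_names is not None:
            return list(self.feature_names)
        return [f"gene{j + 1:04d}" for j in range(self.n_features)]


@dataclass
class AnnotationScheme:
    """How one annotation column is derived from the true labels.

    kind: ``identity`` | ``merge`` (mapping label -> group label) |
    ``noisy`` (each cell relabeled uniformly at random with probability ε) |
    ``split`` (mapping population -> list of subpopulation names, assigned
    uniformly at random).
    """

    name: str
    kind: str = "identity"
    mapping: dict | None = None
    epsilon: float = 0.0
    split: dict | None = None


@dataclass
class ScenarioSpec:
    n_cells: int
    populations: list[tuple[str, float]]
    adt: AdtParams = field(default_factory=AdtParams)
    rna: RnaParams = field(default_factory=RnaParams)
    annotation_schemes: list[AnnotationScheme] = field(
        default_factory=lambda: [AnnotationScheme("truth", "identity")]
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValidationError(f"n_cells must be >= 1, got {self.n_cells}")
        if not self.populations:
            raise ValidationError("populations must be non-empty")
        props = np.array([p for _, p in self.populations], dtype=float)
        if not np.isfinite(props).all() or (props <= 0).any():
            raise ValidationError("population proportions must be finite and positive")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"population proportions must sum to 1 (got {props.sum():.12f})"
            )
        if self.adt.n_features < 1 or self.rna.n_features < 1:
            raise ValidationError("n_features must be >= 1 for both modalities")
        if not np.isfinite(self.adt.sigma) or self.adt.sigma <= 0:
            raise ValidationError(f"adt.sigma must be finite and > 0, got {self.adt.sigma}")
        if not np.isfinite(self.rna.dispersion) or self.rna.dispersion < 0:
            raise ValidationError(f"rna.dispersion must be finite and >= 0")
        pop_names = {n for n, _ in self.populations}
        for scheme in self.annotation_schemes:
            if scheme.kind not in {"identity", "merge", "noisy", "split"}:
                raise ValidationError(f"unknown scheme kind {scheme.kind!r}")
            if scheme.kind == "noisy" and not (0.0 <= scheme.epsilon < 1.0):
                raise ValidationError(
                    f"scheme {scheme.name!r}: epsilon must be in [0, 1), got {scheme.epsilon}"
                )
            if scheme.kind == "merge" and not scheme.mapping:
                raise ValidationError(f"scheme {scheme.name!r}: merge needs a mapping")
            if scheme.kind == "split" and not scheme.split:
                raise ValidationError(f"scheme {scheme.name!r}: split needs a mapping")
        for (pop, feat) in list(self.adt.shifts) + list(self.rna.shifts):
            if pop not in pop_names:
                raise ValidationError(f"shift references unknown population {pop!r}")


@dataclass
class GroundTruth:
    """Everything the generator knows that an analysis should recover."""

    true_labels: np.ndarray
    adt_markers: dict[str, list[str]]
    rna_markers: dict[str, list[str]]
    planted_adt_d: dict  # (population, feature) -> true standardized effect
    planted_rna_lfc: dict  # (population, feature) -> log-fold shift on NB mean
    planted_rna_target_d: dict  # (population, feature) -> calibrated target d
    scheme_kinds: dict[str, str]
    confusion: dict  # (scheme_a, scheme_b) -> {label_a: {label_b: count}}
    params: dict

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_labels": [str(x) for x in self.true_labels],
            "adt_markers": self.adt_markers,
            "rna_markers": self.rna_markers,
            "planted_adt_d": {f"{p}::{f}": v for (p, f), v in self.planted_adt_d.items()},
            "planted_rna_lfc": {f"{p}::{f}": v for (p, f), v in self.planted_rna_lfc.items()},
            "planted_rna_target_d": {
                f"{p}::{f}": v for (p, f), v in self.planted_rna_target_d.items()
            },
            "scheme_kinds": self.scheme_kinds,
            "confusion": {f"{a}::{b}": m for (a, b), m in self.confusion.items()},
            "params": self.params,
        }
        Path(path).write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )


# -- effect-size calibration for NB counts ------------------------------------


def _lognorm_moments(mean: float, dispersion: float, scale_factor: float,
                     tail: float = 1e-10) -> tuple[float, float]:
    """Mean and variance of log1p(scale_factor * C) for C ~ NB(mean, dispersion).

    Computed by direct summation of the NB pmf (Poisson when dispersion=0)
    over the bulk of its support.  ``scale_factor`` is the (approximately
    constant) per-cell library normalization multiplier.
    """
    if dispersion > 0:
        r = 1.0 / dispersion
        dist = stats.nbinom(r, r / (r + mean))
    else:
        dist = stats.poisson(mean)
    hi = int(dist.ppf(1 - tail)) + 1
    c = np.arange(hi + 1)
    p = dist.pmf(c)
    x = np.log1p(scale_factor * c)
    m = float(np.sum(p * x))
    v = float(np.sum(p * x * x) - m * m)
    return m, v


def lfc_for_target_d(
    target_d: float, base_mean: float, dispersion: float, scale_factor: float
) -> float:
    """Log-fold shift on an NB mean that yields Cohen's d ≈ target on the
    log-normalized scale (shifted group vs unshifted group).

    Solved numerically: d(lfc) is monotone in lfc, so a bracketing root
    search on the semi-analytic moments suffices.
    """
    m0, v0 = _lognorm_moments(base_mean, dispersion, scale_factor)

    def realized(lfc: float) -> float:
        m1, v1 = _lognorm_moments(base_mean * np.exp(lfc), dispersion, scale_factor)
        return (m1 - m0) / np.sqrt((v0 + v1) / 2.0)

    lo, hi = 1e-6, 0.5
    while realized(hi) < target_d:
        hi *= 2.0
        if hi > 20:
            raise ValidationError(
                f"cannot reach d={target_d} by shifting mean {base_mean} upward"
            )
    return float(optimize.brentq(lambda l: realized(l) - target_d, lo, hi, xtol=1e-6))


# -- generation ---------------------------------------------------------------


def _derive_scheme(
    scheme: AnnotationScheme, true_labels: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    if scheme.kind == "identity":
        return true_labels.copy()
    if scheme.kind == "merge":
        return np.array([scheme.mapping.get(x, x) for x in true_labels], dtype=object)
    if scheme.kind == "noisy":
        labels = true_labels.copy()
        uniq = sorted(pd.unique(true_labels))
        if len(uniq) < 2 or scheme.epsilon == 0.0:
            return labels
        flip = rng.random(len(labels)) < scheme.epsilon
        for i in np.flatnonzero(flip):
            others = [u for u in uniq if u != labels[i]]
            labels[i] = others[rng.integers(len(others))]
        return labels
    if scheme.kind == "split":
        labels = true_labels.copy()
        for pop, subnames in scheme.split.items():
            idx = np.flatnonzero(true_labels == pop)
            labels[idx] = rng.choice(np.array(subnames, dtype=object), size=len(idx))
        return labels
    raise ValidationError(f"unknown scheme kind {scheme.kind!r}")  # pragma: no cover


def generate(spec: ScenarioSpec) -> tuple[MultimodalDataset, GroundTruth]:
    """Draw one dataset from a scenario specification, fully seed-deterministic.

    Cells are assigned to populations by proportion; ADT values are
    baseline + planted shift + Normal(0, σ) on the normalized scale; RNA raw
    counts are negative binomial with planted log-fold shifts on the mean,
    then log-CP10K normalized; every annotation scheme in the spec becomes
    one annotation column.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells
    pop_names = np.array([p for p, _ in spec.populations], dtype=object)
    props = np.array([w for _, w in spec.populations], dtype=float)
    true_labels = rng.choice(pop_names, size=n, p=props / props.sum())

    # --- ADT: direct simulation on the normalized scale
    adt_features = spec.adt.resolved_feature_names()
    adt_index = {f: j for j, f in enumerate(adt_features)}
    adt = np.full((n, spec.adt.n_features), float(spec.adt.baseline))
    for (pop, feat), delta in spec.adt.shifts.items():
        adt[true_labels == pop, adt_index[feat]] += delta
    adt += rng.normal(0.0, spec.adt.sigma, size=adt.shape)

    # --- RNA: NB counts then log-CP10K
    rna_features = spec.rna.resolved_feature_names()
    rna_index = {f: j for j, f in enumerate(rna_features)}
    if spec.rna.mean is None:
        base_mean = rng.lognormal(np.log(2.0), 1.0, size=spec.rna.n_features)
    else:
        base_mean = np.asarray(spec.rna.mean, dtype=float).copy()
    per_cell_mean = np.broadcast_to(base_mean, (n, spec.rna.n_features)).copy()
    for (pop, feat), lfc in spec.rna.shifts.items():
        per_cell_mean[true_labels == pop, rna_index[feat]] *= np.exp(lfc)
    if spec.rna.dispersion > 0:
        r = 1.0 / spec.rna.dispersion
        lam = rng.gamma(shape=r, scale=per_cell_mean / r)
    else:
        lam = per_cell_mean
    counts = rng.poisson(lam)
    zero_cells = counts.sum(axis=1) == 0
    if zero_cells.any():  # vanishingly rare at realistic feature counts
        logger.warning("generate: bumping %d all-zero cell(s)", int(zero_cells.sum()))
        counts[zero_cells, 0] = 1
    rna_matrix, kept = aio.lognorm_counts(counts)
    assert kept.all()
    rna_matrix = ExpressionMatrix(rna_matrix.values, rna_features)

    # --- annotation schemes
    columns = {}
    for scheme in spec.annotation_schemes:
        columns[scheme.name] = _derive_scheme(scheme, true_labels, rng)
    annotations = pd.DataFrame(columns)

    dataset = MultimodalDataset(
        [f"cell{i + 1:06d}" for i in range(n)],
        {"RNA": rna_matrix, "ADT": ExpressionMatrix(adt, adt_features)},
        annotations,
    )

    # --- ground truth bookkeeping
    adt_markers: dict[str, list[str]] = {}
    for (pop, feat), delta in spec.adt.shifts.items():
        adt_markers.setdefault(pop, []).append(feat)
    rna_markers: dict[str, list[str]] = {}
    for (pop, feat), lfc in spec.rna.shifts.items():
        rna_markers.setdefault(pop, []).append(feat)
    confusion: dict = {}
    names = list(columns)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            tab = pd.crosstab(pd.Series(columns[a]), pd.Series(columns[b]))
            confusion[(a, b)] = {
                str(la): {str(lb): int(tab.loc[la, lb]) for lb in tab.columns if tab.loc[la, lb]}
                for la in tab.index
            }
    truth = GroundTruth(
        true_labels=true_labels,
        adt_markers={p: sorted(v) for p, v in adt_markers.items()},
        rna_markers={p: sorted(v) for p, v in rna_markers.items()},
        planted_adt_d={
            k: float(v / spec.adt.sigma) for k, v in spec.adt.shifts.items()
        },
        planted_rna_lfc={k: float(v) for k, v in spec.rna.shifts.items()},
        planted_rna_target_d={},
        scheme_kinds={s.name: s.kind for s in spec.annotation_schemes},
        confusion=confusion,
        params={
            "n_cells": n,
            "populations": [[p, float(w)] for p, w in spec.populations],
            "adt": {"n_features": spec.adt.n_features, "baseline": spec.adt.baseline,
                    "sigma": spec.adt.sigma},
            "rna": {"n_features": spec.rna.n_features, "dispersion": spec.rna.dispersion},
            "seed": spec.seed,
        },
    )
    return dataset, truth


# -- ready-made scenarios -----------------------------------------------------


def differential_scenario(
    seed: int,
    n_groups: int = 4,
    cells_per_group: int = 100,
    n_rna_features: int = 2000,
    n_adt_features: int = 30,
    rna_markers_per_group: int = 5,
    adt_markers_per_group: int = 2,
    effect_size: float = 2.0,
    dispersion: float = 0.5,
    noise_epsilon: float = 0.05,
) -> tuple[MultimodalDataset, GroundTruth]:
    """Several groups, each with planted upregulated markers at a known d.

    Each group gets ``rna_markers_per_group`` genes whose NB mean is shifted
    by a log-fold change calibrated so the standardized effect on the
    log-normalized scale is ≈ ``effect_size`` against every other group, and
    ``adt_markers_per_group`` proteins shifted by exactly
    ``effect_size × σ``.  Two annotation schemes are included: the truth and
    a noisy copy (label noise ``noise_epsilon``).
    """
    groups = [f"group{i + 1}" for i in range(n_groups)]
    planted_base_mean = 4.0
    rna_features = [f"gene{j + 1:04d}" for j in range(n_rna_features)]
    adt_features = [f"ADT{j + 1:02d}" for j in range(n_adt_features)]

    # fix planted genes' base mean so one calibrated lfc applies to all
    rng_means = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    base_mean = rng_means.lognormal(np.log(2.0), 1.0, size=n_rna_features)
    n_planted = n_groups * rna_markers_per_group
    if n_planted > n_rna_features:
        raise ValidationError("more planted markers than RNA features")
    base_mean[:n_planted] = planted_base_mean
    scale_factor = 1e4 / float(base_mean.sum())
    lfc = lfc_for_target_d(effect_size, planted_base_mean, dispersion, scale_factor)

    rna_shifts, adt_shifts = {}, {}
    for gi, g in enumerate(groups):
        for m in range(rna_markers_per_group):
            rna_shifts[(g, rna_features[gi * rna_markers_per_group + m])] = lfc
        for m in range(adt_markers_per_group):
            feat = adt_features[gi * adt_markers_per_group + m]
            adt_shifts[(g, feat)] = effect_size * 0.5  # sigma = 0.5 below
    spec = ScenarioSpec(
        n_cells=n_groups * cells_per_group,
        populations=[(g, 1.0 / n_groups) for g in groups],
        adt=AdtParams(n_features=n_adt_features, baseline=1.0, sigma=0.5,
                      shifts=adt_shifts, feature_names=adt_features),
        rna=RnaParams(n_features=n_rna_features, mean=base_mean,
                      dispersion=dispersion, shifts=rna_shifts,
                      feature_names=rna_features),
        annotation_schemes=[
            AnnotationScheme("truth", "identity"),
            AnnotationScheme("noisy", "noisy", epsilon=noise_epsilon),
        ],
        seed=int(seed),
    )
    dataset, truth = generate(spec)
    truth.planted_rna_target_d = {k: float(effect_size) for k in rna_shifts}
    truth.params["calibrated_lfc"] = float(lfc)
    truth.params["effect_size"] = float(effect_size)
    return dataset, truth


def isoform_scenario(
    seed: int,
    n_cells: int = 500,
    n_rna_features: int = 2000,
    effect_size: float = 2.0,
) -> tuple[MultimodalDataset, GroundTruth]:
    """Two T-cell-like subpopulations a transcriptome cannot tell apart.

    "naive-like" and "memory-like" share an identical RNA mean profile but
    are separated (true d = ``effect_size``) in two anti-correlated planted
    ADT features, ``CD45RA_like`` (high in naive) and ``CD45RO_like`` (high
    in memory) — the protein-isoform situation where two states differ at
    the surface-protein level but not in gene expression.  A third "other"
    population (20% of cells) carries genuine RNA and ADT differences, so
    both annotation schemes keep ≥ 2 labels.

    Scheme ``adt_based`` distinguishes the subpopulations; scheme
    ``rna_based`` merges them into one "central-memory-like" label,
    producing the two-links-into-one-node crosstab shape.
    """
    sigma = 0.5
    adt_features = ["CD45RA_like", "CD45RO_like"] + [f"ADT{j:02d}" for j in range(3, 31)]
    rna_features = [f"gene{j + 1:04d}" for j in range(n_rna_features)]
    adt_shifts = {
        ("naive-like", "CD45RA_like"): effect_size * sigma,
        ("memory-like", "CD45RO_like"): effect_size * sigma,
        ("other", "ADT03"): effect_size * sigma,
        ("other", "ADT04"): effect_size * sigma,
    }
    # "other" is RNA-distinct; naive vs memory have zero planted RNA shifts
    rng_means = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    base_mean = rng_means.lognormal(np.log(2.0), 1.0, size=n_rna_features)
    base_mean[:20] = 4.0
    scale_factor = 1e4 / float(base_mean.sum())
    lfc = lfc_for_target_d(effect_size, 4.0, 0.5, scale_factor)
    rna_shifts = {("other", rna_features[j]): lfc for j in range(20)}

    spec = ScenarioSpec(
        n_cells=n_cells,
        populations=[("naive-like", 0.4), ("memory-like", 0.4), ("other", 0.2)],
        adt=AdtParams(n_features=30, baseline=1.0, sigma=sigma,
                      shifts=adt_shifts, feature_names=adt_features),
        rna=RnaParams(n_features=n_rna_features, mean=base_mean, dispersion=0.5,
                      shifts=rna_shifts, feature_names=rna_features),
        annotation_schemes=[
            AnnotationScheme("adt_based", "identity"),
            AnnotationScheme(
                "rna_based", "merge",
                mapping={"naive-like": "central-memory-like",
                         "memory-like": "central-memory-like"},
            ),
        ],
        seed=int(seed),
    )
    dataset, truth = generate(spec)
    truth.params["effect_size"] = float(effect_size)
    truth.params["calibrated_lfc"] = float(lfc)
    return dataset, truth


def write_bundle(
    dataset: MultimodalDataset, truth: GroundTruth, out_dir: str | Path
) -> Path:
    """Write a dataset as MTX bundles (one directory per modality) +
    metadata.csv + ground_truth.json — the on-disk form of a simulation."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in dataset.modalities:
        aio.write_mtx_bundle(dataset, out_dir / name, modality=name, write_metadata=False)
    meta = dataset.annotations.copy()
    meta.insert(0, "barcode", dataset.cell_ids)
    meta.to_csv(out_dir / "metadata.csv", index=False)
    truth.to_json(out_dir / "ground_truth.json")
    return out_dir
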