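"""Synthetic inputs with known ground truth for every pipeline stage.

The expression generator emulates a small two-group miRNA microarray study:
~12,000 probes interrogating ~534 miRNAs (≈22 replicate probes per miRNA,
the ratio of the emulated platform), three treated and three control arrays,
log-normal intensities split into a detectable majority above a background
level of 30 and an undetectable remainder below it, and a caller-chosen set
of spiked miRNAs whose treated-group mean is shifted by a signed linear-scale
fold change.  Probe effects are drawn once per probe and shared across
samples, so replicate probes of one miRNA are correlated and the
probe→miRNA collapse stage has realistic work to do.

Companion generators produce a miRNA→gene target-score table (0–100 scores,
miRDB-style), GMT gene sets with an optionally planted enriched set, and
replicate assay series with controllable fold change, noise and injected
gross outliers.  Every generator consumes a single seeded NumPy Generator,
so identical configuration and seed give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .expression_io import (
    AssaySeries,
    ExpressionMatrix,
    GeneSetCollection,
    ProbeAnnotation,
)

#: detectable miRNA fraction emulating 343 detectable of 534 assayed
DEFAULT_DETECTABLE_FRACTION = 343 / 534


@dataclass(frozen=True)
class SimulationConfig:
    """Study design and noise model for the expression generator.

    ``background_level`` is on the linear intensity scale; ``noise_sd`` and
    ``probe_effect_sd`` are log2-scale standard deviations; ``spiked_mirnas``
    maps miRNA ids to signed linear fold changes (|fc| >= 1, negative = down
    in treated).  ``probes_per_mirna`` overrides the n_probes/n_mirnas split
    when given.
    """

    n_probes: int = 12033
    n_mirnas: int = 534
    probes_per_mirna: int | None = None
    n_treated: int = 3
    n_control: int = 3
    background_level: float = 30.0
    detectable_fraction: float = DEFAULT_DETECTABLE_FRACTION
    spiked_mirnas: tuple[tuple[str, float], ...] = ()
    noise_sd: float = 0.25
    probe_effect_sd: float = 0.25
    seed: int = 0
    # log10 offsets of miRNA baselines relative to background
    detectable_offset: tuple[float, float] = (0.5, 2.0)
    undetectable_offset: tuple[float, float] = (-1.5, -0.3)

    def __post_init__(self) -> None:
        if min(self.n_probes, self.n_mirnas, self.n_treated, self.n_control) < 1:
            raise ValueError("counts must be positive")
        if self.n_probes < self.n_mirnas:
            raise ValueError("n_probes must be >= n_mirnas")
        if self.n_mirnas < len(self.spiked_mirnas):
            raise ValueError("more spiked miRNAs than miRNAs")
        if not 0.0 <= self.detectable_fraction <= 1.0:
            raise ValueError("detectable_fraction must lie in [0, 1]")
        if self.noise_sd < 0 or self.probe_effect_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        names = [m for m, _ in self.spiked_mirnas]
        if len(set(names)) != len(names):
            raise ValueError("duplicate spiked miRNA id")
        for mirna, fc in self.spiked_mirnas:
            if abs(fc) < 1.0:
                raise ValueError(
                    f"spiked fold change for {mirna!r} must satisfy |fc| >= 1"
                )


@dataclass(frozen=True)
class GroundTruth:
    """Per-miRNA spike status and true signed fold change (1.0 for nulls)."""

    records: dict[str, tuple[bool, float]] = field(hash=False)

    def is_differential(self, mirna_id: str) -> bool:
        return self.records[mirna_id][0]

    def true_fc(self, mirna_id: str) -> float:
        return self.records[mirna_id][1]

    @property
    def differential_ids(self) -> list[str]:
        return [m for m, (d, _) in self.records.items() if d]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mirna_id": list(self.records),
                "is_differential": [d for d, _ in self.records.values()],
                "true_fc": [f for _, f in self.records.values()],
            }
        )


def mirna_names(n: int) -> list[str]:
    return [f"miR-sim-{i + 1:04d}" for i in range(n)]


def _linear_shift(fc: float) -> float:
    return fc if fc >= 1 else 1.0 / abs(fc)  # |fc| >= 1 enforced upstream


def generate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ProbeAnnotation, GroundTruth]:
    """Simulate a probe-level two-group expression matrix with known truth.

    Probe intensity = miRNA group mean × probe effect × 2^N(0, noise_sd),
    with the miRNA baseline placed above or below background according to its
    detectability and the treated-group mean shifted by the spiked fold
    change on the linear scale.
    """
    rng = np.random.default_rng(config.seed)
    mirnas = mirna_names(config.n_mirnas)
    spiked = dict(config.spiked_mirnas)
    unknown = [m for m in spiked if m not in set(mirnas)]
    if unknown:
        raise ValueError(f"spiked miRNA(s) not among simulated ids: {unknown[:5]}")

    # detectability: spiked miRNAs are always detectable (an undetectable
    # spike would be filtered out and could never be recovered)
    n_detectable = int(round(config.detectable_fraction * config.n_mirnas))
    n_detectable = max(n_detectable, len(spiked))
    spiked_idx = [mirnas.index(m) for m in spiked]
    others = [i for i in range(config.n_mirnas) if i not in set(spiked_idx)]
    extra = rng.choice(len(others), size=n_detectable - len(spiked_idx),
                       replace=False) if n_detectable > len(spiked_idx) else []
    detectable = np.zeros(config.n_mirnas, dtype=bool)
    detectable[spiked_idx] = True
    detectable[[others[i] for i in np.asarray(extra, dtype=int)]] = True

    lo_d, hi_d = config.detectable_offset
    lo_u, hi_u = config.undetectable_offset
    offsets = np.where(
        detectable,
        rng.uniform(lo_d, hi_d, size=config.n_mirnas),
        rng.uniform(lo_u, hi_u, size=config.n_mirnas),
    )
    baseline = config.background_level * 10.0 ** offsets

    shift = np.ones(config.n_mirnas)
    for m, fc in spiked.items():
        shift[mirnas.index(m)] = _linear_shift(fc)
    mean_control = baseline
    mean_treated = baseline * shift

    # probe → miRNA assignment: balanced round robin
    if config.probes_per_mirna is not None:
        n_probes = config.probes_per_mirna * config.n_mirnas
    else:
        n_probes = config.n_probes
    probe_mirna_idx = np.arange(n_probes) % config.n_mirnas
    probe_ids = [f"probe-{i + 1:06d}" for i in range(n_probes)]
    annotation = ProbeAnnotation(
        {p: mirnas[j] for p, j in zip(probe_ids, probe_mirna_idx)}
    )

    probe_effect = 2.0 ** rng.normal(0.0, config.probe_effect_sd, size=n_probes)
    n_samples = config.n_treated + config.n_control
    sample_ids = [f"FA_{i + 1}" for i in range(config.n_treated)] + [
        f"CT_{i + 1}" for i in range(config.n_control)
    ]
    groups = {s: ("treated" if s.startswith("FA") else "control") for s in sample_ids}

    group_mean = np.empty((n_probes, n_samples))
    group_mean[:, : config.n_treated] = mean_treated[probe_mirna_idx, None]
    group_mean[:, config.n_treated :] = mean_control[probe_mirna_idx, None]
    noise = 2.0 ** rng.normal(0.0, config.noise_sd, size=(n_probes, n_samples))
    values = group_mean * probe_effect[:, None] * noise

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                     columns=sample_ids),
        groups,
    )
    truth = GroundTruth(
        {m: (m in spiked, spiked.get(m, 1.0)) for m in mirnas}
    )
    return matrix, annotation, truth


# ---------------------------------------------------------------------------
# target table


def generate_target_table(
    mirnas: Sequence[str],
    genes: Sequence[str],
    seed: int = 0,
    score_distribution: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    targets_per_mirna: tuple[int, int] = (25, 350),
) -> pd.DataFrame:
    """Random miRNA→gene pairs with confidence scores in [0, 100].

    Each miRNA targets a uniformly sized random subset of the gene universe;
    scores come from ``score_distribution(rng, n)`` (default: uniform on
    [0, 100]).  Every (miRNA, gene) pair appears at most once.
    """
    if not mirnas or not genes:
        raise ValueError("mirnas and genes must be non-empty")
    lo, hi = targets_per_mirna
    if not 1 <= lo <= hi:
        raise ValueError("targets_per_mirna bounds must satisfy 1 <= lo <= hi")
    rng = np.random.default_rng(seed)
    sample = score_distribution or (lambda r, n: r.uniform(0.0, 100.0, size=n))
    genes = list(genes)
    rows = []
    for mirna in mirnas:
        k = int(rng.integers(lo, min(hi, len(genes)) + 1))
        chosen = rng.choice(len(genes), size=k, replace=False)
        scores = np.asarray(sample(rng, k), dtype=float)
        if ((scores < 0) | (scores > 100)).any():
            raise ValueError("score_distribution produced scores outside [0, 100]")
        rows.extend(
            {"mirna_id": mirna, "gene_id": genes[g], "score": s}
            for g, s in zip(chosen, scores)
        )
    return pd.DataFrame(rows, columns=["mirna_id", "gene_id", "score"])


# ---------------------------------------------------------------------------
# gene sets


def generate_gene_sets(
    genes: Sequence[str],
    n_sets: int,
    enriched_set: tuple[str, Sequence[str]] | None = None,
    seed: int = 0,
    set_size: tuple[int, int] = (10, 50),
) -> GeneSetCollection:
    """Random named gene sets, optionally with one planted enriched set.

    The planted set contains every listed target gene plus random fill up to
    the sampled set size, guaranteeing a detectable over-representation
    signal for those targets.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    genes = list(genes)
    universe = frozenset(genes)
    rng = np.random.default_rng(seed)
    lo, hi = set_size
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for i in range(n_sets):
        k = int(rng.integers(lo, min(hi, len(genes)) + 1))
        members = frozenset(genes[j] for j in rng.choice(len(genes), size=k,
                                                         replace=False))
        sets[f"SET-{i + 1:03d}"] = ("random gene set", members)
    if enriched_set is not None:
        name, targets = enriched_set
        targets = list(dict.fromkeys(targets))
        stray = set(targets) - universe
        if stray:
            raise ValueError(
                f"enriched set genes outside the universe: {sorted(stray)[:5]}"
            )
        k = int(rng.integers(max(lo, len(targets)), max(hi, len(targets)) + 1))
        fill_pool = [g for g in genes if g not in set(targets)]
        n_fill = min(max(k - len(targets), 0), len(fill_pool))
        fill = [fill_pool[j] for j in rng.choice(len(fill_pool), size=n_fill,
                                                 replace=False)]
        sets[name] = ("planted enriched set", frozenset(targets) | frozenset(fill))
    return GeneSetCollection(sets, universe)


# ---------------------------------------------------------------------------
# assay replicates


def generate_assay_replicates(
    n_treated: int,
    n_control: int,
    true_ratio: float,
    cv: float,
    n_outliers: int = 0,
    seed: int = 0,
    baseline: float = 1.0,
) -> tuple[AssaySeries, AssaySeries, list[tuple[str, int]]]:
    """Replicate assay values for two conditions plus injected-outlier truth.

    Control replicates are Normal(baseline, cv·baseline); treated replicates
    are Normal(baseline·true_ratio, cv·baseline·true_ratio).  ``n_outliers``
    replicates (positions drawn across both arms) are replaced by gross
    deviations at 10× the arm's maximum; their (condition, index) pairs are
    returned as truth.
    """
    if n_treated < 2 or n_control < 2:
        raise ValueError("need >= 2 replicates per condition")
    if true_ratio <= 0:
        raise ValueError("true_ratio must be positive")
    if cv <= 0:
        raise ValueError("cv must be positive")
    if n_outliers >= min(n_treated, n_control):
        raise ValueError("n_outliers must be smaller than the replicate count")
    rng = np.random.default_rng(seed)
    mu_t = baseline * true_ratio
    treated = rng.normal(mu_t, cv * mu_t, size=n_treated)
    control = rng.normal(baseline, cv * baseline, size=n_control)

    outliers: list[tuple[str, int]] = []
    if n_outliers:
        slots = [("treated", i) for i in range(n_treated)] + [
            ("control", i) for i in range(n_control)
        ]
        chosen = rng.choice(len(slots), size=n_outliers, replace=False)
        for c in sorted(int(i) for i in chosen):
            condition, idx = slots[c]
            arm = treated if condition == "treated" else control
            arm[idx] = 10.0 * np.max(np.abs(arm))
            outliers.append((condition, idx))
    return (
        AssaySeries("treated", treated),
        AssaySeries("control", control),
        outliers,
    )
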