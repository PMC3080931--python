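"""Differential miRNA expression by signal-to-noise-ratio permutation testing.

For each miRNA the group separation is scored with the signal-to-noise ratio

    SNR = (mu_treated - mu_control) / (sigma_treated + sigma_control),

computed on log2(intensity + 1); the signed fold change is computed on the
linear-scale group means and reported as the ratio when >= 1 and as its
negative reciprocal otherwise (so -2 means halved in treated samples).

Significance comes from a permutation null: sample→group relabelings that
preserve the group sizes are enumerated exhaustively when few enough (a
3-vs-3 design has C(6,3) = 20 of them), otherwise sampled without
replacement.  A single miRNA's 20 relabelings can never push an empirical
p-value below 1/20, so p-values are *smoothed* by pooling the null statistics
of all miRNAs, giving resolution ~1/(18·m).  The observed labeling and its
mirror are excluded from the pool: under the null they are exchangeable with
every other relabeling (so calibration is unaffected), but for truly
differential miRNAs they carry the signal itself and would contaminate the
shared null, masking weaker true positives whenever many miRNAs respond.

A miRNA is called differential when all three criteria hold: |FC| >= fc_cut
(boundary inclusive), p < p_cut and BH-adjusted FDR < fdr_cut (both strict).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .expression_io import ExpressionMatrix

DEFAULT_SIGMA_FLOOR = 1e-8


@dataclass(frozen=True)
class GroupSummary:
    """Per-group mean/SD on the scale the SNR is computed on (log2)."""

    mu_treated: float
    mu_control: float
    sigma_treated: float
    sigma_control: float


@dataclass(frozen=True)
class PermutationScheme:
    """How the permutation null is built.

    ``mode`` is ``"exhaustive"`` (every distinct relabeling once) or
    ``"sampled"`` (``n_permutations`` distinct relabelings drawn without
    replacement, seeded).  :func:`permutation_null` switches to exhaustive
    automatically whenever the distinct-relabeling count does not exceed the
    requested number of permutations.
    """

    mode: str = "auto"
    n_permutations: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("auto", "exhaustive", "sampled"):
            raise ValueError(f"unknown permutation mode {self.mode!r}")
        if self.mode != "exhaustive" and self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass
class NullDistribution:
    """Per-relabeling, per-miRNA SNR statistics.

    ``stats`` has one row per relabeling and one column per miRNA.
    ``assignments`` lists, per relabeling, the sample indices assigned to the
    treated group; ``identity_index``/``complement_index`` locate the observed
    assignment and its mirror among them (−1 when absent, possible only in
    sampled mode).
    """

    stats: np.ndarray
    assignments: list[tuple[int, ...]]
    identity_index: int
    complement_index: int
    mode: str

    @property
    def n_relabelings(self) -> int:
        return self.stats.shape[0]

    def pool(self, exclude_signal_splits: bool = True) -> np.ndarray:
        """Flattened null pool across miRNAs and relabelings.

        With ``exclude_signal_splits`` (the default) the observed assignment
        and its mirror are left out so that true effects cannot leak into the
        null.
        """
        if not exclude_signal_splits:
            return self.stats.ravel()
        drop = {i for i in (self.identity_index, self.complement_index) if i >= 0}
        keep = [i for i in range(self.n_relabelings) if i not in drop]
        if not keep:
            raise ValueError("null pool empty after excluding signal-bearing splits")
        return self.stats[keep].ravel()


# ---------------------------------------------------------------------------
# elementary statistics


def signed_fold_change(mean_treated: float, mean_control: float) -> float:
    """Treated/control ratio, as r when r >= 1 and -1/r otherwise."""
    if mean_treated <= 0 or mean_control <= 0:
        raise ValueError(
            f"group means must be positive, got {mean_treated} / {mean_control}"
        )
    r = mean_treated / mean_control
    return r if r >= 1 else -1.0 / r


def _floored_sigma(sd: np.ndarray, mu: np.ndarray, sigma_floor: float,
                   relative_floor: bool) -> np.ndarray:
    sd = np.maximum(sd, sigma_floor)
    if relative_floor:
        sd = np.maximum(sd, 0.2 * np.abs(mu))
    return sd


def snr_statistic(
    treated_values,
    control_values,
    sigma_floor: float = DEFAULT_SIGMA_FLOOR,
    relative_floor: bool = False,
) -> tuple[float, GroupSummary]:
    """SNR of one miRNA with sample (n−1) standard deviations.

    Each group SD is floored at ``sigma_floor``; with ``relative_floor`` it is
    additionally floored at 0.2·|group mean| (the originating tool's
    convention, off by default).
    """
    a = np.asarray(treated_values, dtype=float)
    b = np.asarray(control_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group for the SNR")
    mu_a, mu_b = a.mean(), b.mean()
    sd_a = _floored_sigma(a.std(ddof=1), mu_a, sigma_floor, relative_floor)
    sd_b = _floored_sigma(b.std(ddof=1), mu_b, sigma_floor, relative_floor)
    snr = (mu_a - mu_b) / (sd_a + sd_b)
    return float(snr), GroupSummary(float(mu_a), float(mu_b), float(sd_a), float(sd_b))


def _snr_rows(values: np.ndarray, treated_mask: np.ndarray, sigma_floor: float,
              relative_floor: bool) -> np.ndarray:
    """Row-wise SNR for a (miRNA × sample) array under one labeling."""
    a = values[:, treated_mask]
    b = values[:, ~treated_mask]
    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
    sd_a = _floored_sigma(a.std(axis=1, ddof=1), mu_a, sigma_floor, relative_floor)
    sd_b = _floored_sigma(b.std(axis=1, ddof=1), mu_b, sigma_floor, relative_floor)
    return (mu_a - mu_b) / (sd_a + sd_b)


# ---------------------------------------------------------------------------
# permutation null


def _enumerate_assignments(n_samples: int, n_treated: int) -> list[tuple[int, ...]]:
    return list(itertools.combinations(range(n_samples), n_treated))


def permutation_null(
    values: np.ndarray,
    treated_mask: np.ndarray,
    scheme: PermutationScheme = PermutationScheme(),
    sigma_floor: float = DEFAULT_SIGMA_FLOOR,
    relative_floor: bool = False,
) -> NullDistribution:
    """SNR statistics for every (or a sample of) group-size-preserving relabelings.

    ``values`` is the (miRNA × sample) array on the SNR scale; ``treated_mask``
    marks the observed treated samples.  Exhaustive mode is chosen whenever
    the distinct-relabeling count C(n, k) does not exceed the requested number
    of permutations.
    """
    values = np.asarray(values, dtype=float)
    treated_mask = np.asarray(treated_mask, dtype=bool)
    n = treated_mask.size
    k = int(treated_mask.sum())
    if values.shape[1] != n:
        raise ValueError("treated_mask length must match the sample count")
    if k < 2 or n - k < 2:
        raise ValueError("need >= 2 samples per group")
    n_distinct = math.comb(n, k)

    mode = scheme.mode
    if mode == "auto":
        mode = "exhaustive" if n_distinct <= scheme.n_permutations else "sampled"
    if mode == "exhaustive":
        assignments = _enumerate_assignments(n, k)
    else:
        rng = np.random.default_rng(scheme.seed)
        n_draw = min(scheme.n_permutations, n_distinct)
        if n_distinct <= 200_000:
            all_assignments = _enumerate_assignments(n, k)
            idx = rng.choice(n_distinct, size=n_draw, replace=False)
            assignments = [all_assignments[i] for i in sorted(idx)]
        else:
            seen: set[tuple[int, ...]] = set()
            while len(seen) < n_draw:
                seen.add(tuple(sorted(rng.choice(n, size=k, replace=False))))
            assignments = sorted(seen)

    identity = tuple(int(i) for i in np.flatnonzero(treated_mask))
    complement = tuple(int(i) for i in np.flatnonzero(~treated_mask)) if n - k == k else None
    identity_index = complement_index = -1
    stats = np.empty((len(assignments), values.shape[0]))
    for r, assign in enumerate(assignments):
        mask = np.zeros(n, dtype=bool)
        mask[list(assign)] = True
        stats[r] = _snr_rows(values, mask, sigma_floor, relative_floor)
        if assign == identity:
            identity_index = r
        elif complement is not None and assign == complement:
            complement_index = r
    return NullDistribution(stats, assignments, identity_index, complement_index, mode)


def smoothed_p(observed_snr: float, null_pool) -> float:
    """Two-sided add-one empirical p: (b + 1)/(N + 1), b = #{|null| >= |obs|}."""
    pool = np.asarray(null_pool, dtype=float).ravel()
    if pool.size == 0:
        raise ValueError("empty null pool")
    b = int(np.count_nonzero(np.abs(pool) >= abs(observed_snr)))
    return (b + 1) / (pool.size + 1)


def smoothed_p_values(
    observed: np.ndarray,
    null: NullDistribution,
    exclude_signal_splits: bool = True,
) -> np.ndarray:
    """Pooled smoothed p-value per miRNA (vectorised :func:`smoothed_p`)."""
    pool = np.sort(np.abs(null.pool(exclude_signal_splits)))
    n = pool.size
    b = n - np.searchsorted(pool, np.abs(np.asarray(observed, dtype=float)),
                            side="left")
    return (b + 1) / (n + 1)


def per_mirna_p_values(observed: np.ndarray, null: NullDistribution) -> np.ndarray:
    """Unpooled per-miRNA permutation p over that miRNA's own relabelings.

    Resolution is limited to ~1/n_relabelings (>= 1/20 in a 3-vs-3 design);
    provided for diagnostics and granularity checks.
    """
    obs = np.abs(np.asarray(observed, dtype=float))
    b = (np.abs(null.stats) >= obs[None, :]).sum(axis=0)
    return (b + 1) / (null.n_relabelings + 1)


# ---------------------------------------------------------------------------
# multiple testing and calls


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted values, returned in input order and capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_differential(
    results: pd.DataFrame,
    fc_cut: float = 1.5,
    p_cut: float = 0.005,
    fdr_cut: float = 0.005,
) -> pd.DataFrame:
    """Apply the three-criterion call and rank the marker table.

    significant ⇔ |fc| >= fc_cut (inclusive) ∧ p < p_cut ∧ fdr < fdr_cut;
    rows are ordered by |fc| descending, then p ascending, then miRNA id.
    """
    out = results.copy()
    out["significant"] = (
        (out["fc"].abs() >= fc_cut)
        & (out["p_value"] < p_cut)
        & (out["fdr"] < fdr_cut)
    )
    order = out.assign(_absfc=out["fc"].abs(), _id=out.index).sort_values(
        by=["_absfc", "p_value", "_id"], ascending=[False, True, True]
    ).index
    out = out.loc[order].drop(columns=[], errors="ignore")
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def select_markers(
    matrix: ExpressionMatrix,
    n_permutations: int = 2000,
    seed: int = 0,
    fc_cut: float = 1.5,
    p_cut: float = 0.005,
    fdr_cut: float = 0.005,
    sigma_floor: float = DEFAULT_SIGMA_FLOOR,
    relative_floor: bool = False,
    exclude_signal_splits: bool = True,
) -> pd.DataFrame:
    """Full marker-selection stage on a miRNA-level expression matrix.

    Returns one row per miRNA (index = miRNA id) with linear-scale group
    means, log2-scale SNR summaries, signed fold change, pooled smoothed
    p-value, BH FDR, the three-criterion significance flag and the rank.
    """
    treated = matrix.samples_in("treated")
    control = matrix.samples_in("control")
    if len(treated) < 2 or len(control) < 2:
        raise ValueError("need >= 2 samples per group")

    linear = matrix.values
    mean_treated = linear[treated].mean(axis=1)
    mean_control = linear[control].mean(axis=1)
    if (mean_treated <= 0).any() or (mean_control <= 0).any():
        bad = linear.index[(mean_treated <= 0) | (mean_control <= 0)][0]
        raise ValueError(f"non-positive group mean for miRNA {bad!r}")
    fc = np.array([signed_fold_change(t, c)
                   for t, c in zip(mean_treated, mean_control)])

    log_values = np.log2(linear.to_numpy() + 1.0)
    treated_mask = np.array([matrix.groups[s] == "treated" for s in matrix.sample_ids])
    observed = _snr_rows(log_values, treated_mask, sigma_floor, relative_floor)
    a, b = log_values[:, treated_mask], log_values[:, ~treated_mask]

    scheme = PermutationScheme(n_permutations=n_permutations, seed=seed)
    null = permutation_null(log_values, treated_mask, scheme,
                            sigma_floor, relative_floor)
    p = smoothed_p_values(observed, null, exclude_signal_splits)
    fdr = benjamini_hochberg(p)

    results = pd.DataFrame(
        {
            "mean_treated": mean_treated,
            "mean_control": mean_control,
            "mu_treated": a.mean(axis=1),
            "mu_control": b.mean(axis=1),
            "sigma_treated": a.std(axis=1, ddof=1),
            "sigma_control": b.std(axis=1, ddof=1),
            "fc": fc,
            "snr": observed,
            "p_value": p,
            "fdr": fdr,
        },
        index=linear.index.rename("mirna_id"),
    )
    return call_differential(results, fc_cut, p_cut, fdr_cut)


# ---------------------------------------------------------------------------
# reporting: mean standardisation + hierarchical clustering


def standardize_and_cluster(
    matrix: ExpressionMatrix, mirna_subset
) -> tuple[list[str], pd.DataFrame]:
    """Row-standardise a miRNA subset and order it by hierarchical clustering.

    Rows are z-scored (constant rows become all zeros); agglomerative
    clustering with average linkage runs on 1 − Pearson correlation between
    standardised rows (zero-variance rows get correlation 0 with every other
    row).  Returns the leaf order and the standardised matrix in that order.
    """
    subset = list(mirna_subset)
    if not subset:
        raise ValueError("mirna_subset must be non-empty")
    sub = matrix.subset(subset).values
    arr = sub.to_numpy()
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    constant = (sd == 0).ravel()
    sd[sd == 0] = 1.0
    z = (arr - mean) / sd
    zdf = pd.DataFrame(z, index=sub.index, columns=sub.columns)

    if len(subset) == 1:
        return subset, zdf
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(z)
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    dist = np.clip(1.0 - corr, 0.0, None)
    condensed = squareform(dist, checks=False)
    order = leaves_list(linkage(condensed, method="average"))
    leaf_ids = [subset[i] for i in order]
    return leaf_ids, zdf.loc[leaf_ids]
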