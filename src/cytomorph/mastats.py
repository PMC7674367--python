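"""Multi-aspect permutation inference on cell-record tables.

For one cell type, descriptor values follow the additive model
``Y_ij = mu + tau_j + eps_ij`` where population *j* may shift the location
(tau) and inflate the scale (sigma²) of every descriptor, and the error
distribution is left unspecified: all inference is permutation-based.

Two aspects are tested for every ordered population pair and every
descriptor domain:

* **location** — is population *j* larger on average than *h*?  The
  partial statistic per descriptor is the difference of animal-level
  means.
* **scatter** — is population *j* more dispersed than *h*?  The partial
  statistic is the difference of animal-level mean absolute deviations
  from the own-animal median (a Brown–Forsythe-type statistic, invariant
  to location shifts by construction).

Cells within an animal are dependent (subject-specific random effect), so
the exchangeable unit is the **animal**: whole animals are relabelled
between populations, and univariate symmetry tests flip signs block-wise
per animal.  Partial p-values are combined across the descriptors of a
domain by nonparametric combination (Fisher or Tippett) on the shared
permutation distribution, and the six directional hypotheses of each 3×3
matrix are adjusted by min-p step-down on that same distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .records import DESCRIPTORS, DOMAINS, validate_records

_EPS = 1e-12


# ---------------------------------------------------------------------------
# Dataset and animal-level summaries
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """Cell records of a single cell type, validated for inference."""

    records: pd.DataFrame
    descriptors: list[str] = field(default_factory=lambda: list(DESCRIPTORS))

    def __post_init__(self) -> None:
        validate_records(self.records)
        if self.records["cell_type"].nunique() > 1:
            raise ValueError("a Dataset holds exactly one cell type")
        per_pop = self.records.groupby("population")["animal_id"].nunique()
        if (per_pop < 2).any():
            bad = per_pop[per_pop < 2].index.tolist()
            raise ValueError(f"populations with fewer than 2 animals: {bad}")

    @property
    def populations(self) -> list[str]:
        return sorted(self.records["population"].unique())


def animal_summaries(records: pd.DataFrame, aspect: str,
                     descriptors: list[str] | None = None):
    """Animal-level summary matrix for one aspect.

    location → per-animal descriptor means; scatter → per-animal mean of
    ``|value − own-animal median|``.  Returns ``(S, labels)`` where S is an
    (animals × descriptors) DataFrame and labels maps animal → population.
    """
    descriptors = descriptors or list(DESCRIPTORS)
    g = records.groupby("animal_id", sort=True)
    if aspect == "location":
        S = g[descriptors].mean()
    elif aspect == "scatter":
        med = g[descriptors].transform("median")
        absdev = (records[descriptors] - med).abs()
        absdev["animal_id"] = records["animal_id"].values
        S = absdev.groupby("animal_id", sort=True)[descriptors].mean()
    else:
        raise ValueError(f"unknown aspect '{aspect}'")
    labels = g["population"].first().loc[S.index]
    return S, labels


# ---------------------------------------------------------------------------
# Univariate block sign-flip test
# ---------------------------------------------------------------------------

@dataclass
class SignFlipResult:
    p_value: float
    statistic: float
    direction: int          # sign of the observed statistic
    n_flips: int
    exhaustive: bool


def sign_flip_test(values, B: int = 999, seed: int = 0) -> SignFlipResult:
    """Two-sided symmetry test of block (per-animal) values around zero.

    The statistic is the mean of the per-animal values; the null flips the
    sign of whole animals jointly.  All 2^n flip patterns are enumerated
    when that is no more work than B random flips; otherwise B random
    patterns plus the identity are used, giving
    ``p = #{|T*| >= |T|} / n_patterns`` which is always at least
    ``1/(B+1)``.
    """
    if B < 99:
        raise ValueError("B must be at least 99")
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("need per-animal values for at least 2 animals")
    n = len(v)
    t_obs = v.mean()
    if n <= 30 and 2**n <= B + 1:
        signs = np.array(np.meshgrid(*([[1.0, -1.0]] * n),
                                     indexing="ij")).reshape(n, -1).T
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([1.0, -1.0], size=(B, n))
        signs = np.vstack([np.ones((1, n)), signs])  # identity always included
        exhaustive = False
    t_null = signs @ v / n
    p = float(np.mean(np.abs(t_null) >= abs(t_obs) - _EPS))
    return SignFlipResult(p, float(t_obs), int(np.sign(t_obs)),
                          len(signs), exhaustive)


# ---------------------------------------------------------------------------
# Pairwise permutation tests
# ---------------------------------------------------------------------------

@dataclass
class PairwiseTest:
    """Partial tests for one directional pairwise comparison.

    ``stat_null`` holds the per-permutation statistic for each descriptor
    (row 0 is the observed labelling); the same relabelings underlie every
    descriptor so the joint null is available for combination.
    """

    partial_p: np.ndarray
    stat_null: np.ndarray   # (n_perm, n_descriptors)
    descriptors: list[str]
    n_perm: int
    exhaustive: bool


def _two_group_selections(n_j: int, n_h: int, B: int, seed: int,
                          exhaustive) -> tuple[np.ndarray, bool]:
    """Boolean selection matrix (rows = relabelings, True = group j).

    Row 0 is the observed labelling (first ``n_j`` units in group j).
    """
    m = n_j + n_h
    n_comb = math.comb(m, n_j)
    if exhaustive == "auto":
        exhaustive = n_comb <= B + 1
    if exhaustive:
        sel = np.zeros((n_comb, m), dtype=bool)
        observed = tuple(range(n_j))
        rows = sorted(combinations(range(m), n_j),
                      key=lambda c: c != observed)  # observed first
        for r, c in enumerate(rows):
            sel[r, list(c)] = True
        return sel, True
    rng = np.random.default_rng(seed)
    sel = np.zeros((B + 1, m), dtype=bool)
    sel[0, :n_j] = True
    for b in range(1, B + 1):
        sel[b, rng.permutation(m)[:n_j]] = True
    return sel, False


def pairwise_partial_tests(data: Dataset | pd.DataFrame, aspect: str,
                           pop_j: str, pop_h: str, direction: str = "greater",
                           B: int = 999, seed: int = 0,
                           descriptors: list[str] | None = None,
                           exchange_unit: str = "animal",
                           exhaustive="auto") -> PairwiseTest:
    """One-sided partial permutation tests, one per descriptor.

    Whole animals are relabelled between the two populations (the
    within-animal dependence travels with the animal); the one-sided
    p-value for ``direction='greater'`` (population j larger than h) is
    the fraction of relabelings whose statistic reaches the observed one,
    the observed labelling always counting — so p >= 1/n_perm.

    ``exchange_unit='cell'`` relabels individual cells instead.  That
    variant ignores the animal-level random effect and is provided to
    demonstrate the resulting type-I inflation, not for inference.
    """
    records = data.records if isinstance(data, Dataset) else data
    descriptors = descriptors or list(DESCRIPTORS)
    if pop_j == pop_h:
        raise ValueError("the two populations must differ")
    sub = records[records["population"].isin([pop_j, pop_h])]
    if sub["population"].nunique() < 2:
        raise ValueError("both populations must be present")

    if exchange_unit == "animal":
        S, labels = animal_summaries(sub, aspect, descriptors)
        values = S.to_numpy()
        is_j = (labels == pop_j).to_numpy()
    elif exchange_unit == "cell":
        if aspect != "location":
            raise ValueError("cell-level exchange supports the location aspect only")
        values = sub[descriptors].to_numpy()
        is_j = (sub["population"] == pop_j).to_numpy()
    else:
        raise ValueError(f"unknown exchange unit '{exchange_unit}'")

    order = np.argsort(~is_j, kind="stable")  # group j first
    values = values[order]
    n_j = int(is_j.sum())
    n_h = len(values) - n_j
    if n_j == 0 or n_h == 0:
        raise ValueError("identical animal sets: one group is empty")

    sel, was_exhaustive = _two_group_selections(n_j, n_h, B, seed, exhaustive)
    w = sel.astype(float)
    mean_j = (w @ values) / n_j
    mean_h = ((1.0 - w) @ values) / n_h
    stat = mean_j - mean_h
    if direction == "less":
        stat = -stat
    elif direction != "greater":
        raise ValueError("direction must be 'greater' or 'less'")
    p = np.mean(stat >= stat[0] - _EPS, axis=0)
    return PairwiseTest(p, stat, list(descriptors), len(sel), was_exhaustive)


# ---------------------------------------------------------------------------
# Nonparametric combination and multiplicity adjustment
# ---------------------------------------------------------------------------

def _significance_levels(stat_null: np.ndarray) -> np.ndarray:
    """Upper-tail attained level of every permutation value, per column.

    ``L[b, k] = #{b': T[b', k] >= T[b, k]} / n_perm`` — the p-value each
    permutation would obtain against the shared null.
    """
    n = stat_null.shape[0]
    L = np.empty_like(stat_null, dtype=float)
    for k in range(stat_null.shape[1]):
        col = stat_null[:, k]
        srt = np.sort(col)
        L[:, k] = (n - np.searchsorted(srt, col - _EPS, side="left")) / n
    return L


def npc_combine(stat_null: np.ndarray, combining: str = "fisher"):
    """Nonparametric combination of partial tests on their joint null.

    The partial statistics of every permutation are first converted to
    attained significance levels; the combining function (Fisher
    ``-2 Σ log p`` or Tippett ``min p``) is evaluated on the observed row
    and on every permutation, and the combined p-value is the upper-tail
    probability of the observed combined statistic.

    Returns ``(combined_p, combined_levels)`` where ``combined_levels[b]``
    is the attained level of permutation b (row 0 = observed, so
    ``combined_levels[0] == combined_p``) — the ingredient for min-p
    step-down adjustment.
    """
    if stat_null.ndim != 2 or stat_null.shape[1] == 0:
        raise ValueError("need at least one partial test")
    L = _significance_levels(stat_null)
    if combining == "fisher":
        psi = -2.0 * np.log(L).sum(axis=1)
    elif combining == "tippett":
        psi = -L.min(axis=1)
    else:
        raise ValueError(f"unknown combining function '{combining}'")
    n = len(psi)
    srt = np.sort(psi)
    levels = (n - np.searchsorted(srt, psi - _EPS, side="left")) / n
    return float(levels[0]), levels


def minp_stepdown(levels: np.ndarray) -> np.ndarray:
    """Westfall–Young free step-down min-p adjustment.

    ``levels`` is (n_perm × n_hypotheses) of combined significance levels
    with the observed values in row 0.  Hypotheses are visited from the
    smallest raw p; each adjusted p is the permutation probability that
    the minimum level over the not-yet-rejected hypotheses reaches the raw
    one, made monotone and never below raw.
    """
    raw = levels[0]
    order = np.argsort(raw, kind="stable")
    adjusted = np.empty_like(raw)
    prev = 0.0
    for i, hyp in enumerate(order):
        rem = order[i:]
        q = float(np.mean(levels[:, rem].min(axis=1) <= raw[hyp] + _EPS))
        prev = max(prev, q, raw[hyp])
        adjusted[hyp] = prev
    return adjusted


def adjust_matrix(raw_p: dict, null_levels: np.ndarray | None = None,
                  hypotheses: list | None = None) -> dict:
    """Adjust the 6 directional p-values of one (aspect, domain) matrix.

    With the shared permutation null available (``null_levels``, columns
    ordered like ``hypotheses``), min-p step-down is used; without it the
    adjustment degrades to Bonferroni–Holm, which is also monotone and
    never below raw.
    """
    hyps = hypotheses or list(raw_p)
    raw = np.array([raw_p[h] for h in hyps])
    if null_levels is not None:
        adj = minp_stepdown(null_levels)
    else:
        order = np.argsort(raw, kind="stable")
        adj = np.empty_like(raw)
        prev = 0.0
        m = len(raw)
        for i, hyp in enumerate(order):
            prev = max(prev, min(1.0, (m - i) * raw[hyp]))
            adj[hyp] = prev
    return {h: min(1.0, float(a)) for h, a in zip(hyps, adj)}


# ---------------------------------------------------------------------------
# Effect estimation (univariate tables)
# ---------------------------------------------------------------------------

@dataclass
class EffectEstimates:
    """Univariate summary: overall means, population shifts and scales.

    ``arrows`` encodes the per-(population, descriptor) sign-flip outcome
    at the chosen level: +1 significantly above the overall mean, -1
    significantly below, 0 no evidence either way.
    """

    mu: pd.Series
    tau: pd.DataFrame        # populations × descriptors
    sigma2: pd.DataFrame
    p_values: pd.DataFrame
    arrows: pd.DataFrame
    alpha: float


def estimate_effects(data: Dataset | pd.DataFrame, B: int = 999, seed: int = 0,
                     alpha: float = 0.01,
                     descriptors: list[str] | None = None) -> EffectEstimates:
    """Estimate the additive model and test each shift by block sign-flip.

    mu is the grand mean over cells; tau_j the population-mean deviation
    from it (summing to zero under cell-count weights); sigma²_j the
    within-population variance of animal-centred residuals.  Each (j, k)
    shift is tested by flipping the per-animal mean deviations block-wise.
    """
    records = data.records if isinstance(data, Dataset) else data
    descriptors = descriptors or list(DESCRIPTORS)
    pops = sorted(records["population"].unique())
    mu = records[descriptors].mean()
    tau = records.groupby("population")[descriptors].mean().loc[pops] - mu
    centred = records[descriptors] - records.groupby(
        "animal_id")[descriptors].transform("mean")
    sigma2 = (centred.assign(population=records["population"].values)
              .groupby("population")[descriptors].var(ddof=1).loc[pops])

    pvals = pd.DataFrame(index=pops, columns=descriptors, dtype=float)
    arrows = pd.DataFrame(0, index=pops, columns=descriptors, dtype=int)
    for jj, pop in enumerate(pops):
        sub = records[records["population"] == pop]
        animal_means = sub.groupby("animal_id")[descriptors].mean()
        if len(animal_means) < 2:
            raise ValueError(f"population '{pop}' has fewer than 2 animals")
        for kk, k in enumerate(descriptors):
            dev = (animal_means[k] - mu[k]).to_numpy()
            res = sign_flip_test(dev, B=B, seed=seed + 1000 * jj + kk)
            pvals.loc[pop, k] = res.p_value
            if res.p_value <= alpha:
                arrows.loc[pop, k] = res.direction
    return EffectEstimates(mu, tau, sigma2, pvals, arrows, alpha)


# ---------------------------------------------------------------------------
# Full multi-aspect analysis
# ---------------------------------------------------------------------------

@dataclass
class TestConfig:
    B: int = 999
    seed: int = 0
    combining: str = "fisher"
    alpha_arrow: float = 0.01
    domains: dict[str, list[str]] = field(default_factory=lambda: dict(DOMAINS))


@dataclass
class PValueMatrix:
    """Directional pairwise p-values for one (aspect, domain).

    Cell (row j, column h) is the one-sided p for "population j is larger
    than population h" (location) or "more dispersed than" (scatter);
    the diagonal is undefined.
    """

    aspect: str
    domain: str
    raw: pd.DataFrame
    adjusted: pd.DataFrame

    def __post_init__(self) -> None:
        off = ~np.eye(len(self.raw), dtype=bool)
        if not ((self.adjusted.to_numpy()[off] + _EPS)
                >= self.raw.to_numpy()[off]).all():
            raise ValueError("adjusted p-values cannot be below raw ones")


@dataclass
class MultiAspectResult:
    matrices: dict          # (aspect, domain) -> PValueMatrix
    effects: EffectEstimates
    populations: list[str]
    config: TestConfig


def multi_aspect_analysis(data: Dataset | pd.DataFrame,
                          config: TestConfig | None = None) -> MultiAspectResult:
    """Location and scatter 3×3 p-value matrices per domain, plus effects.

    Each pairwise comparison relabels only the animals of its own two
    populations (exchangeability between *those* groups is what the pair's
    null asserts; mixing in a third population with real effects would
    distort the reference distribution).  Within a pair, one set of
    relabelings is shared by every descriptor and by both directions, so
    nonparametric combination sees the joint null; across pairs the
    relabelings are drawn independently with synchronized counts, and the
    min-p step-down adjustment runs on the stacked levels.
    """
    config = config or TestConfig()
    if not isinstance(data, Dataset):
        data = Dataset(data)
    pops = data.populations
    matrices: dict = {}
    for a_i, aspect in enumerate(("location", "scatter")):
        S, labels = animal_summaries(data.records, aspect)
        values = S.to_numpy()
        lab = labels.to_numpy()
        # one relabeling set per unordered pair; both directions share it
        pair_stats: dict[tuple[str, str], np.ndarray] = {}
        for p_i, (j, h) in enumerate(combinations(pops, 2)):
            in_pair = np.isin(lab, [j, h])
            vals = values[in_pair]
            is_j = lab[in_pair] == j
            order = np.argsort(~is_j, kind="stable")
            vals = vals[order]
            n_j = int(is_j.sum())
            n_h = len(vals) - n_j
            rng = np.random.default_rng([config.seed, a_i, p_i])
            sel = np.zeros((config.B + 1, len(vals)), dtype=bool)
            sel[0, :n_j] = True
            for b in range(1, config.B + 1):
                sel[b, rng.permutation(len(vals))[:n_j]] = True
            w = sel.astype(float)
            stat = (w @ vals) / n_j - ((1.0 - w) @ vals) / n_h
            pair_stats[(j, h)] = stat
            pair_stats[(h, j)] = -stat
        for domain, descs in config.domains.items():
            cols = [DESCRIPTORS.index(d) for d in descs]
            hyps = [(j, h) for j in pops for h in pops if j != h]
            raw = {}
            levels = np.empty((config.B + 1, len(hyps)))
            for idx, (j, h) in enumerate(hyps):
                stat = pair_stats[(j, h)][:, cols]
                p_comb, lev = npc_combine(stat, config.combining)
                raw[(j, h)] = p_comb
                levels[:, idx] = lev
            adjusted = adjust_matrix(raw, null_levels=levels, hypotheses=hyps)
            raw_df = pd.DataFrame(np.nan, index=pops, columns=pops)
            adj_df = pd.DataFrame(np.nan, index=pops, columns=pops)
            for (j, h) in hyps:
                raw_df.loc[j, h] = raw[(j, h)]
                adj_df.loc[j, h] = adjusted[(j, h)]
            matrices[(aspect, domain)] = PValueMatrix(aspect, domain,
                                                      raw_df, adj_df)
    effects = estimate_effects(data.records, B=config.B, seed=config.seed,
                               alpha=config.alpha_arrow)
    return MultiAspectResult(matrices, effects, pops, config)
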