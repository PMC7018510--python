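"""Lineage-potency inference for single labeled hemogenic endothelial cells.

Each fish is scored by the presence or absence of GFP⁺ T lymphocytes and
GFP⁺ myeloid cells, regardless of how many cells were counted, giving a
2×2 category per fish.  In labeled fish the category reflects the latent
lineage of the one heat-shocked cell — bipotent (TM), myeloid-only (M),
T-only (T) or no traced progeny (none) — OR'ed with spontaneous background
labeling that also appears in unheated control fish.  Background positivity
is modeled as independent Bernoulli events per channel with rates
(β_T, β_M) shared between groups.

The lineage simplex θ and the background rates are estimated by maximizing
the joint multinomial log-likelihood of the category counts in both groups,
so the control cohort disciplines the background correction.  Boundary
estimates (e.g. θ_T = 0) are legitimate and reported as such.

Also provided: nonparametric bootstrap confidence intervals and the
Mann–Whitney–Wilcoxon rank-sum test used to compare the (decidedly
non-normal) GFP⁺ cell-count distributions between groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm as normal_dist
from scipy.stats import rankdata

__all__ = [
    "CATEGORIES",
    "FishRecord",
    "CohortCounts",
    "LineageEstimate",
    "RankSumResult",
    "classify_fish",
    "model_category_probs",
    "joint_loglik",
    "fit_mle",
    "bootstrap_ci",
    "rank_sum_test",
    "labeling_efficiency",
]

#: presence/absence categories, order fixed everywhere in this module
CATEGORIES = ("T+M+", "T+M-", "T-M+", "T-M-")

#: lineage classes indexing theta: bipotent, myeloid-only, T-only, none
THETA_LABELS = ("theta_tm", "theta_m", "theta_t", "theta_0")

_P_CLIP = 1e-9


@dataclass(frozen=True)
class FishRecord:
    """One fish: group membership and GFP⁺ cell counts in the two channels."""

    id: str
    group: Literal["labeled", "control"]
    t_count: int
    m_count: int

    def __post_init__(self) -> None:
        if self.group not in ("labeled", "control"):
            raise ValueError(f"group must be 'labeled' or 'control', got {self.group!r}")
        if self.t_count < 0 or self.m_count < 0:
            raise ValueError("cell counts must be nonnegative integers")


def classify_fish(record: FishRecord, threshold: int = 1) -> str:
    """2×2 presence/absence category of one fish.

    A channel is positive iff its count reaches ``threshold`` (default 1:
    any GFP⁺ cell is signal); the magnitude of the count carries no further
    information for classification.
    """
    if threshold < 1:
        raise ValueError("presence threshold must be >= 1")
    t_pos = record.t_count >= threshold
    m_pos = record.m_count >= threshold
    return f"T{'+' if t_pos else '-'}M{'+' if m_pos else '-'}"


@dataclass(frozen=True)
class CohortCounts:
    """Per-group 2×2 category counts, in :data:`CATEGORIES` order."""

    labeled: np.ndarray
    control: np.ndarray

    def __post_init__(self) -> None:
        for name in ("labeled", "control"):
            arr = np.asarray(getattr(self, name), dtype=int)
            if arr.shape != (4,) or np.any(arr < 0):
                raise ValueError(f"{name} counts must be 4 nonnegative integers")
            object.__setattr__(self, name, arr)

    @property
    def n_labeled(self) -> int:
        return int(self.labeled.sum())

    @property
    def n_control(self) -> int:
        return int(self.control.sum())

    @classmethod
    def from_records(cls, records: pd.DataFrame, threshold: int = 1) -> "CohortCounts":
        """Tabulate a cohort table with columns group, t_count, m_count.

        Any hidden simulation-truth columns are ignored by construction:
        only the observable counts enter.
        """
        counts = {"labeled": np.zeros(4, int), "control": np.zeros(4, int)}
        for row in records.itertuples(index=False):
            rec = FishRecord(str(getattr(row, "id", "")), row.group,
                             int(row.t_count), int(row.m_count))
            counts[rec.group][CATEGORIES.index(classify_fish(rec, threshold))] += 1
        return cls(labeled=counts["labeled"], control=counts["control"])


def _validate_params(theta: np.ndarray, beta_t: float, beta_m: float) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (4,):
        raise ValueError("theta must have 4 entries (TM, M, T, none)")
    if np.any(theta < -1e-12) or abs(theta.sum() - 1.0) > 1e-8:
        raise ValueError("theta must be a probability simplex (sum 1, entries >= 0)")
    for b in (beta_t, beta_m):
        if not 0.0 <= b <= 1.0:
            raise ValueError("background rates must lie in [0, 1]")
    return np.clip(theta, 0.0, 1.0)


def _labeled_mixing_matrix(beta_t: float, beta_m: float) -> np.ndarray:
    """M with P_labeled = M @ theta; rows = categories, columns = lineages."""
    bt, bm = beta_t, beta_m
    return np.array(
        [
            [1.0, bt, bm, bt * bm],
            [0.0, 0.0, 1.0 - bm, bt * (1.0 - bm)],
            [0.0, 1.0 - bt, 0.0, (1.0 - bt) * bm],
            [0.0, 0.0, 0.0, (1.0 - bt) * (1.0 - bm)],
        ]
    )


def model_category_probs(
    theta: Sequence[float],
    beta_t: float,
    beta_m: float,
    group: Literal["labeled", "control"] = "labeled",
) -> np.ndarray:
    """Category probabilities of the background-corrected lineage model.

    Control fish are positive in a channel only through background, so their
    categories are products of independent Bernoulli(β) outcomes.  Labeled
    fish are positive if their lineage implies the channel or background
    fires; marginalizing the lineage class gives a mixture linear in θ.
    Sums to 1 for every valid parameter point.
    """
    theta_arr = _validate_params(np.asarray(theta, float), beta_t, beta_m)
    if group == "control":
        bt, bm = beta_t, beta_m
        return np.array(
            [bt * bm, bt * (1 - bm), (1 - bt) * bm, (1 - bt) * (1 - bm)]
        )
    if group != "labeled":
        raise ValueError("group must be 'labeled' or 'control'")
    return _labeled_mixing_matrix(beta_t, beta_m) @ theta_arr


def joint_loglik(
    theta: Sequence[float],
    beta_t: float,
    beta_m: float,
    counts: CohortCounts,
) -> float:
    """Joint multinomial log-likelihood of both groups at the given parameters.

    Constant multinomial coefficients are omitted (they do not depend on the
    parameters).  A category observed with probability exactly zero yields
    −inf, returned as a value rather than raised, so optimizers and callers
    can branch on it.
    """
    ll = 0.0
    for group, n in (("labeled", counts.labeled), ("control", counts.control)):
        p = model_category_probs(theta, beta_t, beta_m, group)
        observed = n > 0
        if np.any(p[observed] == 0.0):
            return float("-inf")
        ll += float(np.sum(n[observed] * np.log(p[observed])))
    return ll


@dataclass(frozen=True)
class LineageEstimate:
    """Fitted lineage simplex, background rates and diagnostics."""

    theta: np.ndarray  # (theta_tm, theta_m, theta_t, theta_0)
    beta_t: float
    beta_m: float
    loglik: float
    converged: bool
    n_labeled: int
    n_control: int
    method: str = "joint"
    ci: dict[str, tuple[float, float]] | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        if abs(theta.sum() - 1.0) > 1e-8:
            raise ValueError("fitted theta must sum to 1 within 1e-8")
        object.__setattr__(self, "theta", theta)

    @property
    def theta_dict(self) -> dict[str, float]:
        return dict(zip(THETA_LABELS, (float(t) for t in self.theta)))

    def to_dict(self) -> dict:
        d = {
            **self.theta_dict,
            "beta_t": self.beta_t,
            "beta_m": self.beta_m,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_labeled": self.n_labeled,
            "n_control": self.n_control,
            "method": self.method,
        }
        if self.ci is not None:
            d["ci"] = {k: list(v) for k, v in self.ci.items()}
        return d


def _neg_loglik_and_grad(
    params: np.ndarray,
    counts: CohortCounts,
    fixed_beta: tuple[float, float] | None,
) -> tuple[float, np.ndarray]:
    """Objective for the optimizer: softmax θ, logistic β, analytic gradient.

    Probabilities are clipped to [1e-9, 1 − 1e-9] before the log so the
    objective stays finite everywhere (−inf is represented by the clip, a
    documented large-negative-sentinel convention).
    """
    z = params[:4]
    z = z - z.max()
    expz = np.exp(z)
    theta = expz / expz.sum()
    if fixed_beta is None:
        bt = float(expit(params[4]))
        bm = float(expit(params[5]))
    else:
        bt, bm = fixed_beta
    bt = min(max(bt, _P_CLIP), 1.0 - _P_CLIP)
    bm = min(max(bm, _P_CLIP), 1.0 - _P_CLIP)

    m_mat = _labeled_mixing_matrix(bt, bm)
    p_lab = np.clip(m_mat @ theta, _P_CLIP, 1.0)
    n_lab = counts.labeled
    p_ctl = np.clip(
        np.array([bt * bm, bt * (1 - bm), (1 - bt) * bm, (1 - bt) * (1 - bm)]),
        _P_CLIP, 1.0,
    )
    n_ctl = counts.control
    ll = float(np.sum(n_lab * np.log(p_lab)) + np.sum(n_ctl * np.log(p_ctl)))

    w = n_lab / p_lab
    g_theta = m_mat.T @ w
    g_z = theta * (g_theta - float(theta @ g_theta))

    if fixed_beta is None:
        dm_dbt = np.array(
            [[0, 1, 0, bm], [0, 0, 0, 1 - bm], [0, -1, 0, -bm], [0, 0, 0, -(1 - bm)]],
            dtype=float,
        )
        dm_dbm = np.array(
            [[0, 0, 1, bt], [0, 0, -1, -bt], [0, 0, 0, 1 - bt], [0, 0, 0, -(1 - bt)]],
            dtype=float,
        )
        g_bt = float(w @ (dm_dbt @ theta))
        g_bm = float(w @ (dm_dbm @ theta))
        g_bt += (n_ctl[0] + n_ctl[1]) / bt - (n_ctl[2] + n_ctl[3]) / (1 - bt)
        g_bm += (n_ctl[0] + n_ctl[2]) / bm - (n_ctl[1] + n_ctl[3]) / (1 - bm)
        grad = np.concatenate([g_z, [g_bt * bt * (1 - bt), g_bm * bm * (1 - bm)]])
    else:
        grad = g_z
    return -ll, -grad


def _params_to_estimate(
    params: np.ndarray,
    counts: CohortCounts,
    fixed_beta: tuple[float, float] | None,
) -> tuple[np.ndarray, float, float]:
    z = params[:4] - params[:4].max()
    theta = np.exp(z) / np.exp(z).sum()
    if fixed_beta is None:
        bt = float(expit(params[4]))
        bm = float(expit(params[5]))
    else:
        bt, bm = fixed_beta
    return theta, bt, bm


def _empirical_start(
    counts: CohortCounts, fixed_beta: tuple[float, float] | None
) -> np.ndarray:
    freq = np.clip(counts.labeled / max(counts.n_labeled, 1), 1e-3, None)
    freq = freq / freq.sum()
    z = np.log(freq)
    if fixed_beta is not None:
        return z
    n_c = max(counts.n_control, 1)
    bt = np.clip((counts.control[0] + counts.control[1]) / n_c, 1e-3, 1 - 1e-3)
    bm = np.clip((counts.control[0] + counts.control[2]) / n_c, 1e-3, 1 - 1e-3)
    return np.concatenate([z, [np.log(bt / (1 - bt)), np.log(bm / (1 - bm))]])


def fit_mle(
    counts: CohortCounts,
    *,
    estimate_background: Literal["joint", "plugin"] = "joint",
    n_starts: int = 10,
    seed: int = 0,
    extra_starts: Sequence[np.ndarray] | None = None,
) -> LineageEstimate:
    """Maximum-likelihood estimate of (θ, β) from both cohorts.

    The simplex is handled by a softmax reparameterization and the rates by
    a logistic one, optimized by L-BFGS with an analytic gradient from
    ``n_starts`` random starts plus one start at the empirical labeled
    frequencies and control rates; the best log-likelihood wins (ties by
    first reached).  Boundary solutions such as θ_T = 0 are admissible.

    ``estimate_background='plugin'`` fixes β at the control-group empirical
    positivity rates and maximizes over θ only; ``'joint'`` (default)
    estimates everything simultaneously.

    When the control group shows no positive fish in either channel the MLE
    is available in closed form — β̂ = 0 and θ̂ equal to the labeled
    empirical category frequencies — and is returned exactly.
    """
    if counts.n_labeled == 0 or counts.n_control == 0:
        raise ValueError("both groups must be nonempty")

    ctl = counts.control
    if ctl[0] + ctl[1] + ctl[2] == 0:
        # categories (++, +-, -+, --) map to lineages (TM, T, M, none)
        theta = counts.labeled[[0, 2, 1, 3]] / counts.n_labeled
        return LineageEstimate(
            theta=theta,
            beta_t=0.0,
            beta_m=0.0,
            loglik=joint_loglik(theta, 0.0, 0.0, counts),
            converged=True,
            n_labeled=counts.n_labeled,
            n_control=counts.n_control,
            method=f"{estimate_background}:closed_form",
        )

    if estimate_background == "plugin":
        n_c = counts.n_control
        fixed = (
            float((ctl[0] + ctl[1]) / n_c),
            float((ctl[0] + ctl[2]) / n_c),
        )
        n_params = 4
    elif estimate_background == "joint":
        fixed = None
        n_params = 6
    else:
        raise ValueError("estimate_background must be 'joint' or 'plugin'")

    rng = np.random.default_rng(seed)
    starts = [_empirical_start(counts, fixed)]
    for _ in range(n_starts):
        s = rng.normal(size=n_params)
        if fixed is None:
            b = rng.uniform(0.005, 0.5, size=2)
            s[4:] = np.log(b / (1 - b))
        starts.append(s)
    if extra_starts is not None:
        starts.extend(np.asarray(s, dtype=float) for s in extra_starts)

    best = None
    for p0 in starts:
        res = minimize(
            _neg_loglik_and_grad,
            p0,
            args=(counts, fixed),
            jac=True,
            method="L-BFGS-B",
            options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    theta, bt, bm = _params_to_estimate(best.x, counts, fixed)
    return LineageEstimate(
        theta=theta,
        beta_t=bt,
        beta_m=bm,
        loglik=-float(best.fun),
        converged=bool(best.success),
        n_labeled=counts.n_labeled,
        n_control=counts.n_control,
        method=estimate_background,
        diagnostics={"n_starts": len(starts), "optimizer_message": str(best.message)},
    )


def bootstrap_ci(
    records: pd.DataFrame,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    *,
    threshold: int = 1,
    estimate_background: Literal["joint", "plugin"] = "joint",
    n_starts_per_fit: int = 1,
) -> tuple[LineageEstimate, dict[str, tuple[float, float]]]:
    """Percentile bootstrap confidence intervals for every model parameter.

    Fish are resampled with replacement within their group; each resample is
    refit starting from the full-data estimate (plus ``n_starts_per_fit``
    random starts).  Degenerate resamples (e.g. a control resample with no
    positives) still refit — via the closed form where it applies — and are
    counted in the diagnostics.

    Returns the full-data estimate (with the intervals attached) and the
    interval dictionary.
    """
    if B < 100:
        raise ValueError("B must be >= 100 for meaningful percentile intervals")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    full_counts = CohortCounts.from_records(records, threshold)
    full_fit = fit_mle(full_counts, estimate_background=estimate_background, seed=seed)

    # pre-classify once; bootstrap then resamples category labels only
    cats = np.array(
        [
            CATEGORIES.index(
                classify_fish(
                    FishRecord(str(getattr(r, "id", "")), r.group,
                               int(r.t_count), int(r.m_count)),
                    threshold,
                )
            )
            for r in records.itertuples(index=False)
        ]
    )
    groups = records["group"].to_numpy()
    lab_cats = cats[groups == "labeled"]
    ctl_cats = cats[groups == "control"]

    warm = _full_fit_start(full_fit, estimate_background)
    rng = np.random.default_rng(seed)
    draws = {k: [] for k in (*THETA_LABELS, "beta_t", "beta_m")}
    n_degenerate = 0
    for _ in range(B):
        lab_res = rng.choice(lab_cats, size=lab_cats.size, replace=True)
        ctl_res = rng.choice(ctl_cats, size=ctl_cats.size, replace=True)
        boot_counts = CohortCounts(
            labeled=np.bincount(lab_res, minlength=4),
            control=np.bincount(ctl_res, minlength=4),
        )
        if boot_counts.control[:3].sum() == 0:
            n_degenerate += 1
        fit = fit_mle(
            boot_counts,
            estimate_background=estimate_background,
            n_starts=n_starts_per_fit,
            seed=int(rng.integers(2**31)),
            extra_starts=[warm] if warm is not None else None,
        )
        for k, v in fit.theta_dict.items():
            draws[k].append(v)
        draws["beta_t"].append(fit.beta_t)
        draws["beta_m"].append(fit.beta_m)

    alpha = 1.0 - level
    ci = {
        k: (
            float(np.quantile(v, alpha / 2)),
            float(np.quantile(v, 1 - alpha / 2)),
        )
        for k, v in draws.items()
    }
    out = LineageEstimate(
        theta=full_fit.theta,
        beta_t=full_fit.beta_t,
        beta_m=full_fit.beta_m,
        loglik=full_fit.loglik,
        converged=full_fit.converged,
        n_labeled=full_fit.n_labeled,
        n_control=full_fit.n_control,
        method=full_fit.method,
        ci=ci,
        diagnostics={**full_fit.diagnostics, "B": B, "n_degenerate_resamples": n_degenerate},
    )
    return out, ci


def _full_fit_start(
    fit: LineageEstimate, estimate_background: str
) -> np.ndarray | None:
    theta = np.clip(fit.theta, 1e-6, None)
    z = np.log(theta / theta.sum())
    if estimate_background == "plugin":
        return z
    bt = np.clip(fit.beta_t, 1e-6, 1 - 1e-6)
    bm = np.clip(fit.beta_m, 1e-6, 1 - 1e-6)
    return np.concatenate([z, [np.log(bt / (1 - bt)), np.log(bm / (1 - bm))]])


@dataclass(frozen=True)
class RankSumResult:
    """Mann–Whitney–Wilcoxon test result: U of the first sample and p-value."""

    u_statistic: float
    p_value: float
    method: str


def rank_sum_test(
    labeled_counts: Sequence[float],
    control_counts: Sequence[float],
    alternative: Literal["two-sided", "greater", "less"] = "two-sided",
) -> RankSumResult:
    """Mann–Whitney–Wilcoxon rank-sum comparison of two count samples.

    U is computed from midranks (ties share their average rank).  For
    combined sample sizes up to 20 the null distribution is enumerated
    exactly over all group assignments, which handles ties correctly; larger
    samples use the normal approximation with tie correction and continuity
    correction.  With every observation identical the test is vacuous and
    p = 1.
    """
    x = np.asarray(labeled_counts, dtype=float)
    y = np.asarray(control_counts, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)  # midranks
    r1 = float(ranks[:n1].sum())
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0

    if np.all(combined == combined[0]):
        return RankSumResult(u, 1.0, "degenerate")

    if n1 + n2 <= 20:
        idx_sums = _all_rank_sums(ranks, n1)
        u_all = idx_sums - n1 * (n1 + 1) / 2.0
        tol = 1e-9
        if alternative == "two-sided":
            p = float(np.mean(np.abs(u_all - mu) >= abs(u - mu) - tol))
        elif alternative == "greater":
            p = float(np.mean(u_all >= u - tol))
        elif alternative == "less":
            p = float(np.mean(u_all <= u + tol))
        else:
            raise ValueError("alternative must be two-sided, greater or less")
        return RankSumResult(u, p, "exact")

    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return RankSumResult(u, 1.0, "degenerate")
    sigma = np.sqrt(sigma2)
    if alternative == "two-sided":
        z = (abs(u - mu) - 0.5) / sigma
        p = float(2.0 * normal_dist.sf(max(z, 0.0)))
    elif alternative == "greater":
        z = (u - mu - 0.5) / sigma
        p = float(normal_dist.sf(z))
    elif alternative == "less":
        z = (u - mu + 0.5) / sigma
        p = float(normal_dist.cdf(z))
    else:
        raise ValueError("alternative must be two-sided, greater or less")
    return RankSumResult(u, min(p, 1.0), "normal_approx")


def _all_rank_sums(ranks: np.ndarray, n1: int) -> np.ndarray:
    """Rank sums of the first group over all C(n, n1) assignments."""
    idx = np.array(list(combinations(range(ranks.size), n1)), dtype=np.intp)
    return ranks[idx].sum(axis=1)


def labeling_efficiency(successes: int, attempts: int) -> float:
    """Single-cell labeling efficiency as a percentage, rounded to 0.1."""
    if attempts <= 0 or successes < 0 or successes > attempts:
        raise ValueError("need 0 <= successes <= attempts with attempts > 0")
    return round(100.0 * successes / attempts, 1)
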