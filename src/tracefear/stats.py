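"""Inference layer: cluster-level permutation tests on trial-averaged time
courses, trial-averaging effect-size calibration (retrodictive validity),
habituation-corrected mixed models, exact noncentral-t power planning, and
printed-summary recomputation helpers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sst

from .design import CS_MINUS, CS_PLUS

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# cluster-level permutation test
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    start_idx: int
    end_idx: int  # inclusive
    mass: float   # sum of |t| over the cluster
    sign: int
    p: float = np.nan


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_obs: np.ndarray
    t_crit: float
    null_max_mass: np.ndarray
    n_permutations: int
    cluster_forming_alpha: float
    seed: int | None

    @property
    def min_p(self) -> float:
        return min((c.p for c in self.clusters), default=1.0)

    @property
    def significant(self) -> bool:
        return self.min_p <= 0.05


def _run_masses(mask: np.ndarray, weights: np.ndarray):
    """Per-row runs of True in ``mask`` (2-D), weighted by ``weights``.

    Returns (rows, starts, ends, masses) with ends exclusive, columns
    relative to each row.
    """
    n_rows, n_cols = mask.shape
    padded = np.zeros((n_rows, n_cols + 2), dtype=np.int8)
    padded[:, 1:-1] = mask
    d = np.diff(padded, axis=1)
    r0, starts = np.nonzero(d == 1)
    r1, ends = np.nonzero(d == -1)
    # starts/ends come in matched order per row
    csum = np.zeros((n_rows, n_cols + 1))
    np.cumsum(np.where(mask, weights, 0.0), axis=1, out=csum[:, 1:])
    masses = csum[r1, ends] - csum[r0, starts]
    return r0, starts, ends, masses


def _paired_t_from_sums(s1: np.ndarray, s2: np.ndarray, n: int) -> np.ndarray:
    """t statistic per column from per-permutation sums of subject
    differences (s1) and squared differences (s2)."""
    mean = s1 / n
    var = (s2 - n * mean**2) / (n - 1)
    var = np.maximum(var, np.finfo(float).tiny)
    return mean / np.sqrt(var / n)


def cluster_permutation_test(
    data: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 10_000,
    forming_alpha: float = 0.05,
    seed: int | None = None,
) -> ClusterResult:
    """Cluster-level random permutation test for a CS+/CS− time course.

    ``data``: (n_subjects, n_trials, n_timepoints) trial time courses.
    ``labels``: (n_subjects, n_trials) boolean, True for CS+.

    The observed statistic is the per-timepoint paired t over subject
    condition means. Clusters are maximal runs of supra-threshold
    same-sign t (point-wise two-tailed ``forming_alpha``), with mass =
    Σ|t|. The null distribution is the maximum cluster mass over the time
    course after shuffling trial labels within each subject (preserving
    per-condition counts); each cluster's p uses the add-one estimator
    p = (1 + #{null ≥ mass}) / (1 + n_perm).
    """
    data = np.asarray(data, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_subj, n_trials, n_tp = data.shape
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    if labels.shape != (n_subj, n_trials):
        raise ValueError("labels shape mismatch")
    n_plus = labels[0].sum()
    if not np.all(labels.sum(axis=1) == n_plus) or n_plus in (0, n_trials):
        raise ValueError("both conditions must be present with equal counts "
                         "across subjects")
    n_minus = n_trials - n_plus

    # observed per-subject condition-mean differences
    diff_obs = np.empty((n_subj, n_tp))
    for s in range(n_subj):
        diff_obs[s] = data[s][labels[s]].mean(axis=0) - data[s][~labels[s]].mean(axis=0)
    t_obs = _paired_t_from_sums(
        diff_obs.sum(axis=0), (diff_obs**2).sum(axis=0), n_subj
    )
    t_crit = float(sst.t.ppf(1.0 - forming_alpha / 2.0, n_subj - 1))

    clusters: list[Cluster] = []
    absr = np.abs(t_obs)[None, :]
    for sign, m in ((1, (t_obs > t_crit)[None, :]), (-1, (t_obs < -t_crit)[None, :])):
        _, starts, ends, masses = _run_masses(m, absr)
        for s0, e0, mass in zip(starts, ends, masses):
            clusters.append(Cluster(int(s0), int(e0) - 1, float(mass), sign))
    clusters.sort(key=lambda c: c.start_idx)

    # permutation null: max cluster mass per shuffle
    rng = np.random.default_rng(seed)
    tot = data.sum(axis=1)          # (n_subj, n_tp)
    sum_d = np.zeros((n_perm, n_tp))
    sum_d2 = np.zeros((n_perm, n_tp))
    base = np.tile(np.arange(n_trials), (n_perm, 1))
    for s in range(n_subj):
        sel = rng.permuted(base, axis=1)[:, :n_plus]
        pick = np.zeros((n_perm, n_trials))
        np.put_along_axis(pick, sel, 1.0, axis=1)
        s_sel = pick @ data[s]       # (n_perm, n_tp)
        d = s_sel / n_plus - (tot[s] - s_sel) / n_minus
        sum_d += d
        sum_d2 += d * d
    t_null = _paired_t_from_sums(sum_d, sum_d2, n_subj)
    abs_null = np.abs(t_null)
    null_max = np.zeros(n_perm)
    for m in (t_null > t_crit, t_null < -t_crit):
        rows, _, _, masses = _run_masses(m, abs_null)
        np.maximum.at(null_max, rows, masses)

    for c in clusters:
        c.p = float((1 + np.sum(null_max >= c.mass)) / (1 + n_perm))
    return ClusterResult(
        clusters=clusters,
        t_obs=t_obs,
        t_crit=t_crit,
        null_max_mass=null_max,
        n_permutations=n_perm,
        cluster_forming_alpha=forming_alpha,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# trial-averaging calibration (retrodictive validity)
# ---------------------------------------------------------------------------

def hedges_correction(df: int) -> float:
    """Small-sample correction factor J: g = J * d."""
    return 1.0 - 3.0 / (4.0 * df - 1.0)


@dataclass
class CalibrationResult:
    """Effect sizes of the first-1..n trial averages.

    ``table`` has one row per n with t, df, p, cohen_d, hedges_g and a
    ``flag`` for degenerate rows; ``best_n`` maximizes |d|; ``confirmation``
    holds the single-row re-evaluation on an independent dataset when run.
    """

    table: pd.DataFrame
    best_n: int
    confirmation: pd.DataFrame | None = None


def _first_n_means(estimates: pd.DataFrame, n: int):
    """Per-subject means of the first n CS+ and CS− trials (presentation
    order within condition). Returns (subjects, mean_plus, mean_minus)."""
    df = estimates.sort_values("trial_index")
    gp = df.groupby(["subject", "condition"])["amplitude"]
    means = gp.apply(lambda s: s.iloc[:n].mean()).unstack("condition")
    means = means.dropna()
    return means.index.to_numpy(), means[CS_PLUS].to_numpy(), means[CS_MINUS].to_numpy()


def _paired_stats(mp: np.ndarray, mm: np.ndarray) -> dict:
    diffs = mp - mm
    n = len(diffs)
    df = n - 1
    sd = float(np.std(diffs, ddof=1))
    if sd == 0 or not np.isfinite(sd):
        if np.allclose(diffs, 0.0):
            return dict(t=0.0, df=df, p=1.0, cohen_d=0.0, hedges_g=0.0, flag="")
        return dict(t=np.nan, df=df, p=np.nan, cohen_d=np.nan,
                    hedges_g=np.nan, flag="zero_variance")
    t = float(np.mean(diffs) / (sd / np.sqrt(n)))
    p = float(2 * sst.t.sf(abs(t), df))
    d = float(np.mean(diffs) / sd)
    return dict(t=t, df=df, p=p, cohen_d=d,
                hedges_g=d * hedges_correction(df), flag="")


def calibrate_trial_average(
    estimates: pd.DataFrame, n_max: int = 15
) -> CalibrationResult:
    """Paired t and effect size of the first-1..n_max trial averages.

    ``estimates`` is a (normalized) trial-estimate table for one dataset.
    For each n, subject means over the first n trials per condition are
    compared by a paired t-test; Cohen's d = mean difference / SD of
    differences; Hedges' g applies the small-sample correction. The n with
    the largest |d| is recorded for confirmation on an independent dataset.
    """
    rows = []
    for n in range(1, n_max + 1):
        _, mp, mm = _first_n_means(estimates, n)
        if len(mp) < 2:
            raise ValueError("need at least 2 subjects with both conditions")
        rows.append({"n": n, **_paired_stats(mp, mm)})
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["cohen_d"])
    if valid.empty:
        # every row degenerate (zero-variance differences): flagged in the
        # table; no n is selectable
        best_n = 0
    else:
        best_n = int(valid.loc[valid["cohen_d"].abs().idxmax(), "n"])
    return CalibrationResult(table=table, best_n=best_n)


def confirm_calibration(
    result: CalibrationResult, estimates2: pd.DataFrame
) -> CalibrationResult:
    """Re-evaluate only the selected n on a second, independent dataset."""
    _, mp, mm = _first_n_means(estimates2, result.best_n)
    conf = pd.DataFrame([{"n": result.best_n, **_paired_stats(mp, mm)}])
    return CalibrationResult(table=result.table, best_n=result.best_n,
                             confirmation=conf)


# ---------------------------------------------------------------------------
# habituation models and the mixed-effects condition test
# ---------------------------------------------------------------------------

@dataclass
class HabituationModel:
    """Across-trial response decay, fitted once and then frozen.

    exponential: amplitude ≈ a · exp(−λ·(trial−1)), λ ≥ 0 (startle EMG);
    linear: amplitude ≈ a + b·(trial−1) (skin conductance).
    The trial regressor for the mixed model is exp(−λ·(trial−1)) or the
    trial index respectively.
    """

    form: str
    lam: float = 0.0        # exponential decay rate per trial
    slope: float = 0.0      # linear slope per trial
    intercept: float = 0.0
    source_dataset: str | None = None

    def trial_regressor(self, trial_index: np.ndarray) -> np.ndarray:
        k = np.asarray(trial_index, dtype=float) - 1.0
        if self.form == "exponential":
            return np.exp(-self.lam * k)
        return k


def fit_habituation(
    estimates: pd.DataFrame,
    form: str = "exponential",
    *,
    dataset_id: str | None = None,
) -> HabituationModel:
    """Fit the across-trial decay to all trials pooled across subjects.

    Exponential: ordinary least squares over (a, λ) with λ ≥ 0, solved by
    profiling a out analytically on a λ grid with local refinement.
    Linear: OLS on the trial index.
    """
    y = estimates["amplitude"].to_numpy(dtype=float)
    k = estimates["trial_index"].to_numpy(dtype=float) - 1.0
    ok = np.isfinite(y)
    y, k = y[ok], k[ok]
    if form == "linear":
        b, a = np.polyfit(k, y, 1)
        return HabituationModel("linear", slope=float(b), intercept=float(a),
                                source_dataset=dataset_id)
    if form != "exponential":
        raise ValueError(f"unknown habituation form {form!r}")

    def rss(lam: float) -> float:
        x = np.exp(-lam * k)
        a = float(x @ y) / float(x @ x)
        r = y - a * x
        return float(r @ r)

    grid = np.linspace(0.0, 1.0, 101)
    losses = [rss(l) for l in grid]
    i = int(np.argmin(losses))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(rss, bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-6})
        lam = float(res.x) if res.fun <= losses[i] else float(grid[i])
    else:
        lam = float(grid[i])
    if rss(0.0) <= rss(lam):
        lam = 0.0
    x = np.exp(-lam * k)
    a = float(x @ y) / float(x @ x)
    return HabituationModel("exponential", lam=lam, intercept=a,
                            source_dataset=dataset_id)


@dataclass
class FixedEffectTest:
    name: str
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta_sq: float


@dataclass
class LmeResult:
    effects: dict[str, FixedEffectTest]
    params: pd.Series
    random_structure: str
    converged: bool
    aic: float
    warnings: list[str] = field(default_factory=list)


def _fit_mixedlm(df: pd.DataFrame, re_formula: str):
    import statsmodels.formula.api as smf

    md = smf.mixedlm(
        "amplitude ~ treg * is_plus", df, groups=df["subject"],
        re_formula=re_formula,
    )
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        fit = md.fit(reml=False)
    msgs = [str(w.message) for w in wlist]
    return fit, msgs


def lme_condition_test(
    estimates: pd.DataFrame,
    habituation: HabituationModel,
    random_structure: str = "intercept_slope",
) -> LmeResult:
    """Mixed-model test of trial, condition, and their interaction.

    The trial regressor is the frozen habituation transform (exponential
    decay regressor or linear index). The model has a random intercept and
    (by default) a random trial slope per subject, estimated by maximum
    likelihood. Each single-df fixed effect is tested by a Wald F with
    denominator df = n_obs − n_subjects − (n_fixed − 1); partial η² =
    F / (F + df_den). A singular random-effects fit falls back to the
    random-intercept model with a logged warning.
    """
    df = estimates.dropna(subset=["amplitude"]).copy()
    df["treg"] = habituation.trial_regressor(df["trial_index"].to_numpy())
    df["is_plus"] = (df["condition"] == CS_PLUS).astype(float)

    re_formula = {"intercept_slope": "~treg", "intercept": "~1"}[random_structure]
    fit, msgs = _fit_mixedlm(df, re_formula)
    structure = random_structure
    singular = any("singular" in m.lower() or "converge" in m.lower() for m in msgs)
    if random_structure == "intercept_slope" and (singular or not fit.converged):
        log.warning("singular random-effects fit; falling back to random "
                    "intercept only")
        fit, msgs2 = _fit_mixedlm(df, "~1")
        msgs += msgs2
        structure = "intercept"

    n_obs = len(df)
    n_subj = df["subject"].nunique()
    n_fixed = 4  # intercept, treg, is_plus, treg:is_plus
    df_den = n_obs - n_subj - (n_fixed - 1)
    name_map = {"trial": "treg", "condition": "is_plus",
                "interaction": "treg:is_plus"}
    effects = {}
    for name, term in name_map.items():
        z = float(fit.params[term] / fit.bse[term])
        F = z * z
        p = float(sst.f.sf(F, 1, df_den))
        effects[name] = FixedEffectTest(
            name=name, F=F, df_num=1, df_den=df_den, p=p,
            partial_eta_sq=F / (F + df_den),
        )
    return LmeResult(
        effects=effects,
        params=fit.params,
        random_structure=structure,
        converged=bool(fit.converged),
        aic=float(fit.aic),
        warnings=msgs,
    )


def select_random_structure(
    estimates: pd.DataFrame, habituation: HabituationModel
) -> str:
    """Pick the random-effects structure by AIC on a training dataset."""
    aics = {}
    for structure in ("intercept", "intercept_slope"):
        try:
            aics[structure] = lme_condition_test(
                estimates, habituation, structure
            ).aic
        except Exception as exc:  # pragma: no cover - estimation failure
            log.warning("structure %s failed: %s", structure, exc)
    return min(aics, key=aics.get)


# ---------------------------------------------------------------------------
# power planning and printed-summary helpers
# ---------------------------------------------------------------------------

@dataclass
class PowerSpec:
    d: float
    alpha: float = 0.05
    power: float = 0.80
    tails: str = "one"
    design: str = "paired"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must be in (0, 1)")
        if self.d <= 0:
            raise ValueError("d must be positive")
        if self.tails not in ("one", "two"):
            raise ValueError("tails must be 'one' or 'two'")
        if self.design not in ("paired", "two_sample"):
            raise ValueError("design must be 'paired' or 'two_sample'")


def _power_at(spec: PowerSpec, n: int) -> float:
    """Exact noncentral-t power at n (pairs, or per-group for two_sample)."""
    if spec.design == "paired":
        df = n - 1
        ncp = spec.d * np.sqrt(n)
    else:
        df = 2 * n - 2
        ncp = spec.d * np.sqrt(n / 2.0)
    alpha = spec.alpha if spec.tails == "one" else spec.alpha / 2.0
    tcrit = sst.t.ppf(1.0 - alpha, df)
    return float(sst.nct.sf(tcrit, df, ncp))


def sample_size(spec: PowerSpec, n_max: int = 1_000_000) -> int:
    """Smallest sample size achieving the requested power.

    Exact noncentral-t computation (never the normal approximation).
    Returns the number of pairs for a paired design, or the TOTAL across
    both (equal) arms for a two-sample design.
    """
    n = 2
    while n <= n_max:
        if _power_at(spec, n) >= spec.power:
            return n if spec.design == "paired" else 2 * n
        n += 1
    raise ValueError("no sample size below n_max achieves the requested power")


def summary_t_and_d(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> dict:
    """Two-sample pooled-variance t and Cohen's d from printed summaries."""
    sp = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    t = (mean1 - mean2) / (sp * np.sqrt(1.0 / n1 + 1.0 / n2))
    df = n1 + n2 - 2
    return {"t": float(t), "df": df, "p": float(2 * sst.t.sf(abs(t), df)),
            "cohen_d": float((mean1 - mean2) / sp)}


def chi2_2x2_yates(a: int, b: int, c: int, d: int) -> dict:
    """2×2 chi-square test with Yates continuity correction."""
    chi2, p, _, _ = sst.chi2_contingency(
        np.array([[a, b], [c, d]]), correction=True
    )
    return {"chi2": float(chi2), "p": float(p)}
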