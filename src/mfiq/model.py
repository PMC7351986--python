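"""Per-level repeated-measures linear mixed models of quartile MFI.

For each cervical level a separate model is fitted:

    MFI ~ group * quartile + age + sex + BMI        (fixed effects)
    + per-participant random intercept and random slope on the numeric
      quartile index (unstructured 2x2 covariance)                 (random)

Group (reference: recovered) and quartile (reference: Q4) enter the fixed
part as categorical factors; the random slope captures inter-participant
differences in the medial->lateral change of MFI without the
over-parameterisation of a full categorical random quartile effect.
Covariates are centred at the sample mean so the intercept and the marginal
group contrasts are evaluated at covariate means. Estimation is restricted
maximum likelihood (statsmodels MixedLM).

Inference: pairwise intra-quartile group contrasts are Wald t-tests on linear
combinations of the fixed effects. Degrees of freedom use a containment-style
rule — between-participant df (participants minus the rank of the
between-participant design) for group contrasts, which are between-participant
comparisons; residual df for the within-participant interaction omnibus. The
df method is recorded in every result. Contrast p-values are unadjusted by
default (Bonferroni available), with alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from mfiq.cohort import GROUPS

REFERENCE_GROUP = "recovered"
REFERENCE_QUARTILE = 4

_BASE_FORMULA = "mfi ~ C(group, Treatment('recovered')) * C(quartile, Treatment(4))"
COVARIATES = ("age_c", "sex_c", "bmi_c")
RE_FORMULA = "~quartile_num"

#: Ordered group pairs reported for every quartile.
CONTRAST_PAIRS = (("severe", "recovered"), ("mild", "recovered"), ("severe", "mild"))

_GROUP_TERM = "C(group, Treatment('recovered'))[T.{g}]"
_INTERACTION_TERM = (
    "C(group, Treatment('recovered'))[T.{g}]:C(quartile, Treatment(4))[T.{q}]"
)

#: Residual variance below which a table is treated as deterministic and the
#: model degenerates to its exact least-squares solution.
_DEGENERATE_MSE = 1e-10


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of the per-level mixed model and its contrasts."""

    alpha: float = 0.05
    adjust: Literal["none", "bonferroni"] = "none"
    reml: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.adjust not in ("none", "bonferroni"):
            raise ValueError(f"unknown adjustment {self.adjust!r}")


@dataclass
class MixedModelResult:
    """Fitted per-level model: estimates, tests and diagnostics."""

    level: str
    fe_params: pd.Series
    fe_se: pd.Series
    cov_fe: pd.DataFrame = field(repr=False)
    variance_components: dict[str, float]
    interaction_test: dict[str, float]
    n_obs: int
    n_participants: int
    df_between: int
    df_resid: int
    groups_present: tuple[str, ...]
    converged: bool
    degenerate: bool
    df_method: str = "containment (between-participant for group contrasts)"

    @property
    def usable(self) -> bool:
        """Whether contrasts may be computed from this fit."""
        return self.converged or self.degenerate


def _prepare(table: pd.DataFrame) -> pd.DataFrame:
    df = table.copy()
    df["quartile"] = df["quartile"].astype(int)
    df["quartile_num"] = df["quartile"].astype(float)
    df["age_c"] = df["age"] - df["age"].mean()
    df["bmi_c"] = df["bmi"] - df["bmi"].mean()
    sex_male = (df["sex"].astype(str) == "male").astype(float)
    df["sex_c"] = sex_male - sex_male.mean()
    return df


def design_formula(df: pd.DataFrame) -> str:
    """Fixed-effects formula for a prepared table.

    Centred covariates with zero variance in the table (e.g. a single-sex
    cohort) are not estimable and are dropped from the design.
    """
    terms = [c for c in COVARIATES if float(df[c].abs().max()) > 0]
    return _BASE_FORMULA + "".join(f" + {c}" for c in terms)


def _between_rank(df: pd.DataFrame) -> int:
    """Rank of the between-participant design (intercept, group dummies, covariates)."""
    per = df.drop_duplicates("participant_id")
    cols = [np.ones(len(per)), per["age_c"].to_numpy(), per["sex_c"].to_numpy(),
            per["bmi_c"].to_numpy()]
    for g in GROUPS:
        if g != REFERENCE_GROUP and g in set(per["group"]):
            cols.append((per["group"] == g).to_numpy(float))
    X = np.column_stack(cols)
    return int(np.linalg.matrix_rank(X))


def fit_level_model(table: pd.DataFrame, spec: ModelSpec = ModelSpec()) -> MixedModelResult:
    """Fit the mixed model for one cervical level.

    Parameters
    ----------
    table : analysis rows of a single level (participant_id, quartile, mfi,
        age, sex, bmi, group).
    spec : ModelSpec

    Notes
    -----
    A table whose least-squares residual variance is numerically zero (a
    noise-free cohort) makes the mixed likelihood singular; it is fitted by
    exact ordinary least squares instead and flagged ``degenerate`` with all
    variance components reported as zero.
    """
    levels_present = sorted(set(table["level"]))
    if len(levels_present) != 1:
        raise ValueError(f"fit_level_model expects a single level, got {levels_present}")
    level = levels_present[0]
    groups_present = tuple(g for g in GROUPS if g in set(table["group"]))
    if len(groups_present) < 2:
        raise ValueError("need at least two recovery groups to fit group contrasts")

    df = _prepare(table)
    n_participants = df["participant_id"].nunique()
    df_between = max(n_participants - _between_rank(df), 1)

    formula = design_formula(df)
    ols = smf.ols(formula, data=df).fit()
    df_resid_ols = int(ols.df_resid)

    if ols.mse_resid < _DEGENERATE_MSE or df_resid_ols <= 0:
        cov = pd.DataFrame(
            np.zeros((len(ols.params),) * 2), index=ols.params.index, columns=ols.params.index
        )
        return MixedModelResult(
            level=level,
            fe_params=ols.params,
            fe_se=pd.Series(0.0, index=ols.params.index),
            cov_fe=cov,
            variance_components={
                "intercept_var": 0.0, "slope_var": 0.0,
                "intercept_slope_cov": 0.0, "residual_var": 0.0,
            },
            interaction_test={"stat": np.nan, "df_num": np.nan, "df_den": np.nan, "p": np.nan},
            n_obs=len(df),
            n_participants=n_participants,
            df_between=df_between,
            df_resid=df_resid_ols,
            groups_present=groups_present,
            converged=True,
            degenerate=True,
        )

    model = smf.mixedlm(formula, data=df, groups=df["participant_id"],
                        re_formula=RE_FORMULA)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(reml=spec.reml, method=["lbfgs", "powell"], maxiter=200)
            converged = bool(fit.converged)
        except (np.linalg.LinAlgError, ValueError):
            fit = None
            converged = False

    if fit is None:
        # Non-converged: report the OLS fixed effects, flagged unusable.
        cov = pd.DataFrame(np.asarray(ols.cov_params()), index=ols.params.index,
                           columns=ols.params.index)
        return MixedModelResult(
            level=level, fe_params=ols.params, fe_se=ols.bse, cov_fe=cov,
            variance_components={}, interaction_test={}, n_obs=len(df),
            n_participants=n_participants, df_between=df_between,
            df_resid=df_resid_ols, groups_present=groups_present,
            converged=False, degenerate=False,
        )

    k_fe = len(fit.fe_params)
    cov_fe = pd.DataFrame(
        np.asarray(fit.cov_params())[:k_fe, :k_fe],
        index=fit.fe_params.index, columns=fit.fe_params.index,
    )
    cov_re = np.asarray(fit.cov_re)
    variance_components = {
        "intercept_var": float(cov_re[0, 0]),
        "slope_var": float(cov_re[1, 1]),
        "intercept_slope_cov": float(cov_re[0, 1]),
        "residual_var": float(fit.scale),
    }

    inter_names = [n for n in fit.fe_params.index if ":" in n]
    df_resid = len(df) - k_fe
    if inter_names:
        L = np.zeros((len(inter_names), k_fe))
        for i, name in enumerate(inter_names):
            L[i, list(fit.fe_params.index).index(name)] = 1.0
        est = L @ fit.fe_params.to_numpy()
        V = L @ cov_fe.to_numpy() @ L.T
        wald = float(est @ np.linalg.solve(V, est))
        f_stat = wald / len(inter_names)
        p = float(stats.f.sf(f_stat, len(inter_names), df_resid))
        interaction_test = {"stat": f_stat, "df_num": float(len(inter_names)),
                            "df_den": float(df_resid), "p": p}
    else:
        interaction_test = {"stat": np.nan, "df_num": np.nan, "df_den": np.nan, "p": np.nan}

    return MixedModelResult(
        level=level,
        fe_params=fit.fe_params,
        fe_se=pd.Series(np.sqrt(np.clip(np.diag(cov_fe), 0.0, None)),
                        index=fit.fe_params.index),
        cov_fe=cov_fe,
        variance_components=variance_components,
        interaction_test=interaction_test,
        n_obs=len(df),
        n_participants=n_participants,
        df_between=df_between,
        df_resid=df_resid,
        groups_present=groups_present,
        converged=converged,
        degenerate=False,
    )


def _contrast_vector(result: MixedModelResult, g1: str, g2: str, quartile: int) -> np.ndarray:
    """L such that L @ beta = EMM(g1, quartile) - EMM(g2, quartile) at covariate means."""
    names = list(result.fe_params.index)
    L = np.zeros(len(names))

    def add(name: str, w: float) -> None:
        L[names.index(name)] += w

    for g, w in ((g1, 1.0), (g2, -1.0)):
        if g == REFERENCE_GROUP:
            continue
        add(_GROUP_TERM.format(g=g), w)
        if quartile != REFERENCE_QUARTILE:
            add(_INTERACTION_TERM.format(g=g, q=quartile), w)
    return L


def group_contrast(
    result: MixedModelResult, g1: str, g2: str, quartile: int
) -> tuple[float, float, float]:
    """Estimated marginal-mean difference g1 - g2 within a quartile: (est, se, p).

    Contrasting a group with itself returns (0, 0, 1) exactly.
    """
    if g1 == g2:
        return 0.0, 0.0, 1.0
    L = _contrast_vector(result, g1, g2, quartile)
    est = float(L @ result.fe_params.to_numpy())
    var = float(L @ result.cov_fe.to_numpy() @ L)
    se = float(np.sqrt(max(var, 0.0)))
    if se == 0.0:
        # Degenerate (noise-free) fit: the estimate is exact.
        p = 1.0 if est == 0.0 else 0.0
        return est, se, p
    t = est / se
    p = float(2.0 * stats.t.sf(abs(t), result.df_between))
    return est, se, p


def pairwise_quartile_contrasts(
    result: MixedModelResult, spec: ModelSpec = ModelSpec()
) -> pd.DataFrame:
    """All pairwise group contrasts within each quartile for one level.

    Returns an empty (but well-formed) table when the fit is unusable.
    Bonferroni adjustment, when requested, multiplies each p by the number of
    contrasts in the level's family.
    """
    columns = ["level", "quartile", "pair", "estimate", "se", "df", "p", "significant"]
    if not result.usable:
        return pd.DataFrame(columns=columns)
    pairs = [(a, b) for a, b in CONTRAST_PAIRS
             if a in result.groups_present and b in result.groups_present]
    rows = []
    for q in (1, 2, 3, 4):
        for g1, g2 in pairs:
            est, se, p = group_contrast(result, g1, g2, q)
            rows.append({
                "level": result.level, "quartile": q, "pair": f"{g1}-{g2}",
                "estimate": est, "se": se, "df": result.df_between, "p": p,
            })
    out = pd.DataFrame(rows)
    if spec.adjust == "bonferroni":
        out["p"] = np.minimum(out["p"] * len(out), 1.0)
    out["significant"] = out["p"] < spec.alpha
    return out[columns]


@dataclass
class LevelSummary:
    """Results across all cervical levels plus the significance matrix."""

    results: dict[str, MixedModelResult]
    contrasts: pd.DataFrame
    significance: pd.DataFrame  # level x quartile x pair -> bool


def run_all_levels(table: pd.DataFrame, spec: ModelSpec = ModelSpec()) -> LevelSummary:
    """Fit one mixed model per cervical level present in the table."""
    levels = sorted(set(table["level"]))
    if not levels:
        raise ValueError("analysis table covers no level")
    results: dict[str, MixedModelResult] = {}
    frames = []
    for level in levels:
        res = fit_level_model(table[table["level"] == level], spec)
        results[level] = res
        frames.append(pairwise_quartile_contrasts(res, spec))
    contrasts = pd.concat(frames, ignore_index=True)
    if contrasts.empty:
        significance = pd.DataFrame(columns=["level", "quartile", "pair", "significant"])
    else:
        significance = contrasts[["level", "quartile", "pair", "significant"]].copy()
    return LevelSummary(results=results, contrasts=contrasts, significance=significance)


@dataclass
class OperatingCharacteristics:
    """Monte-Carlo operating characteristics of the per-level contrast tests."""

    rejection: pd.DataFrame  # (level, quartile, pair) -> rate, mc_se
    q1_highest_rate: float  # fraction of replicates with Q1 the top sample-mean quartile everywhere
    all_level_q1_power: dict[str, float]  # pair -> fraction of reps significant at every level
    n_reps: int


def power_typeI_study(
    n_severe: int,
    n_mild: int,
    n_recovered: int,
    profiles: Mapping | None = None,
    measurement_sd: float = 1.0,
    n_reps: int = 100,
    seed: int = 0,
    levels: Sequence[str] | None = None,
    spec: ModelSpec = ModelSpec(),
) -> OperatingCharacteristics:
    """Simulate replicate cohorts and tally contrast rejection rates.

    Each replicate draws fresh metadata and a fresh analysis table from the
    given ground-truth profiles, runs the per-level models and records which
    pairwise contrasts reject at ``spec.alpha``. Monte-Carlo standard errors
    accompany every rate.
    """
    from mfiq.synthetic import default_profiles, generate_metadata, simulate_analysis_table

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    profiles = profiles or default_profiles()
    levels = list(levels) if levels is not None else sorted({lv for _, lv in profiles})

    tallies: dict[tuple[str, int, str], int] = {}
    q1_highest = 0
    all_q1: dict[str, int] = {}
    for rep in range(n_reps):
        rep_seed = (seed * 100003 + rep) % (2**31 - 1)
        participants = generate_metadata(n_severe, n_mild, n_recovered, seed=rep_seed)
        table = simulate_analysis_table(
            participants, profiles, measurement_sd=measurement_sd,
            seed=rep_seed, levels=levels,
        )
        summary = run_all_levels(table, spec)
        for row in summary.contrasts.itertuples():
            key = (row.level, row.quartile, row.pair)
            tallies[key] = tallies.get(key, 0) + int(row.significant)

        means = table.groupby(["group", "level", "quartile"])["mfi"].mean()
        q1_top = all(
            means[g, lv, 1] == means[g, lv].max()
            for g in set(table["group"]) for lv in levels
        )
        q1_highest += int(q1_top)
        sig = summary.contrasts
        for pair in sig["pair"].unique():
            q1_rows = sig[(sig["quartile"] == 1) & (sig["pair"] == pair)]
            if len(q1_rows) == len(levels) and q1_rows["significant"].all():
                all_q1[pair] = all_q1.get(pair, 0) + 1

    rows = []
    for (level, q, pair), k in sorted(tallies.items()):
        rate = k / n_reps
        rows.append({
            "level": level, "quartile": q, "pair": pair,
            "rate": rate, "mc_se": float(np.sqrt(rate * (1 - rate) / n_reps)),
        })
    rejection = pd.DataFrame(rows, columns=["level", "quartile", "pair", "rate", "mc_se"])
    return OperatingCharacteristics(
        rejection=rejection,
        q1_highest_rate=q1_highest / n_reps,
        all_level_q1_power={pair: k / n_reps for pair, k in sorted(all_q1.items())},
        n_reps=n_reps,
    )
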