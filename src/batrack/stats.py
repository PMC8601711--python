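"""Block-design aggregation and the mixed-model analyses.

Acoustic events are aggregated into the alternating 5-min control/deterrent
block design (12 blocks per night, nested in night, nested in site), and
the response families of the original analyses are fitted: Poisson or
negative binomial GLMMs for counts (family chosen by a conditional Pearson
dispersion check), Gaussian LMMs for speed, distance, Box-Cox height, log
length and the call parameters, and a beta GLMM with cloglog link for the
tortuosity value. Inference is by likelihood-ratio tests between nested
ML fits, model selection by small-sample AICc (richer model kept only when
more than 2 units better), and call-parameter p-values carry a Bonferroni
correction for the six responses tested.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .glmm import (BetaCloglog, DegenerateDataError, GLMMResult,
                   NegativeBinomial, Poisson, fit_glmm)

__all__ = [
    "ModelResult",
    "SparseDataError",
    "count_passes",
    "aggregate_blocks",
    "fit_count_model",
    "fit_trajectory_models",
    "fit_call_param_model",
    "aicc",
    "model_select",
    "lrt",
    "percent_reduction",
    "composition_table",
]

log = logging.getLogger(__name__)

N_CALL_RESPONSES = 6  # Bonferroni m for the call-parameter family of tests


class SparseDataError(ValueError):
    """Too few events to model (the <20 passes/night exclusion)."""


@dataclass
class ModelResult:
    """Uniform summary of one fitted mixed model."""

    name: str
    family: str
    link: str
    fixed: pd.DataFrame             # term, estimate, se, z
    random: pd.DataFrame            # group, variance, sd, pct_of_total
    loglik: float
    aicc: float
    n: int
    k_params: int
    lrt_treatment: dict | None = None   # chi2, df, p (and p_adjusted if any)
    extra: dict = field(default_factory=dict)

    def coef(self, term: str) -> float:
        row = self.fixed.loc[self.fixed["term"] == term, "estimate"]
        if row.empty:
            raise KeyError(term)
        return float(row.iloc[0])


# ---------------------------------------------------------------------------
# Pass counting and block aggregation
# ---------------------------------------------------------------------------

def count_passes(call_times_s) -> int:
    """Count bat passes from sorted call timestamps: a new pass starts when
    the gap since the previous call exceeds 1 s."""
    t = np.asarray(list(call_times_s), dtype=float)
    if t.size == 0:
        return 0
    if np.any(np.diff(t) < 0):
        raise ValueError("timestamps must be sorted")
    return int(1 + np.sum(np.diff(t) > 1.0))


def aggregate_blocks(files: pd.DataFrame, files_per_block: int = 30,
                     exclude_first: int = 6) -> pd.DataFrame:
    """Aggregate per-10-s-file counts into per-block counts.

    ``files`` needs columns site, night, block, file (1-based position in
    the block), species_group, event_type, count. The first minute of each
    5-min block (files 1..6) is excluded to minimise spill-over from the
    previous block, leaving 24 files summed per block. Blocks without
    exactly ``files_per_block`` distinct file positions raise ``ValueError``
    naming the block. Treatment labels are taken from a ``treatment`` column
    when present, otherwise derived from the alternating control-first
    schedule (odd block = control).
    """
    req = {"site", "night", "block", "file", "species_group", "event_type", "count"}
    missing = req - set(files.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    for (site, night, block), grp in files.groupby(["site", "night", "block"]):
        positions = set(grp["file"].unique())
        if positions != set(range(1, files_per_block + 1)):
            raise ValueError(
                f"block {site}/{night}/{block} has {len(positions)} file "
                f"positions, expected {files_per_block}")
    kept = files[files["file"] > exclude_first]
    keys = ["site", "night", "block", "species_group", "event_type"]
    out = kept.groupby(keys, as_index=False)["count"].sum()
    if "treatment" in files.columns:
        tr = files[keys[:3] + ["treatment"]].drop_duplicates()
        out = out.merge(tr, on=keys[:3], how="left")
    else:
        out["treatment"] = np.where(out["block"] % 2 == 1, "control", "deterrent")
    return out[["site", "night", "block", "treatment",
                "species_group", "event_type", "count"]]


# ---------------------------------------------------------------------------
# Information criteria and LRT
# ---------------------------------------------------------------------------

def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Second-order Akaike information criterion."""
    if n <= k + 1:
        raise ValueError("AICc requires n > k + 1")
    return float(-2.0 * log_likelihood + 2 * k + 2.0 * k * (k + 1) / (n - k - 1))


def model_select(candidates: list[tuple[str, ModelResult]]
                 ) -> tuple[str, ModelResult, pd.DataFrame]:
    """Select among nested candidates ordered simplest to richest.

    A richer model is kept only when its AICc is lower by more than 2 than
    the currently selected (simpler) model. Returns (name, model, table).
    """
    if not candidates:
        raise ValueError("no candidate models")
    table = pd.DataFrame([(nm, m.loglik, m.k_params, m.aicc)
                          for nm, m in candidates],
                         columns=["model", "loglik", "k", "aicc"])
    best_name, best = candidates[0]
    for nm, m in candidates[1:]:
        if best.aicc - m.aicc > 2.0:
            best_name, best = nm, m
    return best_name, best, table


def lrt(full, reduced) -> tuple[float, int, float]:
    """Likelihood-ratio test between a model containing a term and the
    nested model without it: chi2 = 2 (l_full - l_reduced), df = parameter
    difference, p from the chi2 upper tail."""
    ll_f, k_f, n_f = full.loglik, full.k_params, full.n
    ll_r, k_r, n_r = reduced.loglik, reduced.k_params, reduced.n
    if n_f != n_r:
        raise ValueError("models were fitted to different data")
    if k_f <= k_r:
        raise ValueError("models are not nested (full must have more parameters)")
    chi2 = max(2.0 * (ll_f - ll_r), 0.0)
    df = k_f - k_r
    return chi2, df, float(sps.chi2.sf(chi2, df))


def bonferroni(p: float, m: int = N_CALL_RESPONSES) -> float:
    return float(min(1.0, p * m))


# ---------------------------------------------------------------------------
# Count models
# ---------------------------------------------------------------------------

def _design(df: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for t in terms:
        if t == "treatment":
            cols.append((df["treatment"].to_numpy() == "deterrent").astype(float))
            names.append("treatment[deterrent]")
        elif t == "block_order":
            cols.append((df["block"].to_numpy(dtype=float) - 6.5) / 5.5)
            names.append("block_order")
        elif t == "distance":
            d = df["distance_from_deterrent_m"].to_numpy(dtype=float)
            cols.append(d - d.mean())  # centred: main effects read at mean d
            names.append("distance")
        elif t == "treatment:distance":
            d = df["distance_from_deterrent_m"].to_numpy(dtype=float)
            cols.append((df["treatment"].to_numpy() == "deterrent")
                        * (d - d.mean()))
            names.append("treatment:distance")
        else:
            raise ValueError(f"unknown term {t!r}")
    return np.column_stack(cols), names


def _nested_groups(df: pd.DataFrame, levels=("site", "night", "block")
                   ) -> dict[str, np.ndarray]:
    groups = {}
    label = None
    for lv in levels:
        part = df[lv].astype(str).to_numpy()
        label = part if label is None else np.char.add(np.char.add(label, ":"), part)
        groups[lv] = label.copy()
    return groups


def _glmm_to_result(name: str, res: GLMMResult, lrt_dict=None, extra=None
                    ) -> ModelResult:
    random = res.random_table()
    if res.family == "gaussian":
        # include the residual variance so percentages span all components
        resid_var = float(np.exp(2.0 * res.aux["log_sd"]))
        var = np.append(random["variance"].to_numpy(), resid_var)
        random = pd.DataFrame({
            "group": list(random["group"]) + ["residual"],
            "variance": var,
            "sd": np.sqrt(var),
            "pct_of_total": 100.0 * var / var.sum(),
        })
    return ModelResult(name=name, family=res.family, link=res.link,
                       fixed=res.fixed_table(), random=random,
                       loglik=res.loglik,
                       aicc=aicc(res.loglik, res.k_params, res.n),
                       n=res.n, k_params=res.k_params,
                       lrt_treatment=lrt_dict, extra=extra or {})


def fit_count_model(blocks: pd.DataFrame, species_group: str,
                    event_type: str = "pass", min_per_night: int = 20,
                    dispersion_threshold: float = 1.5,
                    include_block_order: bool = True) -> ModelResult:
    """Poisson or negative-binomial GLMM for one species group's counts.

    Fixed effects: deterrent treatment and time-block order; random
    intercepts for block nested in night nested in site. The family is
    Poisson unless the conditional Pearson dispersion ratio of the Poisson
    fit exceeds ``dispersion_threshold``, in which case the NB2 model is
    used. Groups with fewer than ``min_per_night`` events per night for the
    majority of nights are refused (:class:`SparseDataError`), as in the
    original exclusion rule. The treatment LRT against the model without
    treatment is attached to the result.
    """
    sub = blocks[(blocks["species_group"] == species_group)
                 & (blocks["event_type"] == event_type)].copy()
    if len(sub) < 20:
        raise SparseDataError(f"only {len(sub)} blocks for {species_group}")
    nightly = sub.groupby(["site", "night"])["count"].sum()
    if (nightly < min_per_night).sum() > len(nightly) / 2:
        raise SparseDataError(
            f"{species_group} {event_type}: fewer than {min_per_night} events "
            "per night for the majority of nights; excluded from modelling")

    terms = ["treatment"] + (["block_order"] if include_block_order else [])
    X, names = _design(sub, terms)
    Xr, names_r = _design(sub, terms[1:])
    groups = _nested_groups(sub)
    y = sub["count"].to_numpy(dtype=float)

    fit_p = fit_glmm(y, X, groups, Poisson(), fe_names=names)
    mu = np.exp(np.clip(fit_p.fitted_eta, -30, 30))
    pearson = float(np.sum((y - mu) ** 2 / np.maximum(mu, 1e-8))
                    / max(len(y) - fit_p.k_params, 1))
    if pearson > dispersion_threshold:
        family = NegativeBinomial()
        fit_full = fit_glmm(y, X, groups, family, fe_names=names)
        fit_red = fit_glmm(y, Xr, groups, family, fe_names=names_r)
    else:
        family = Poisson()
        fit_full = fit_p
        fit_red = fit_glmm(y, Xr, groups, family, fe_names=names_r)
    chi2, df, p = lrt(fit_full, fit_red)
    return _glmm_to_result(
        f"{species_group} {event_type}", fit_full,
        lrt_dict={"chi2": chi2, "df": df, "p": p},
        extra={"pearson_dispersion": pearson, "species_group": species_group,
               "event_type": event_type})


# ---------------------------------------------------------------------------
# Gaussian LMMs (statsmodels MixedLM) and trajectory models
# ---------------------------------------------------------------------------

def _fit_lmm(df: pd.DataFrame, response: str, fe_terms: list[str],
             vc_levels: list[str], name: str, extra: dict | None = None
             ) -> tuple[ModelResult, object]:
    """ML LinearMixedModel with a site random intercept and nested variance
    components; returns the summary and the raw statsmodels result."""
    import statsmodels.formula.api as smf

    data = df.copy()
    label = data["site"].astype(str)
    data["_site"] = label
    for lv in vc_levels:
        label = label + ":" + data[lv].astype(str)
        data[f"_{lv}_id"] = label
    vcf = {lv: f"0 + C(_{lv}_id)" for lv in vc_levels}
    formula = f"{response} ~ " + " + ".join(fe_terms) if fe_terms else f"{response} ~ 1"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups="_site", re_formula="1",
                            vc_formula=vcf)
        fit = model.fit(reml=False, method="lbfgs", maxiter=300, disp=False)
    p = len(fit.fe_params)
    k = p + 1 + len(vc_levels) + 1  # + site var + vc vars + residual var
    fixed = pd.DataFrame({"term": fit.fe_params.index,
                          "estimate": fit.fe_params.values,
                          "se": fit.bse_fe.values,
                          "z": fit.fe_params.values / fit.bse_fe.values})
    scale = float(fit.scale)
    site_var = float(np.asarray(fit.cov_re)[0, 0])
    vc_vars = {lv: float(fit.vcomp[i] if hasattr(fit, "vcomp") else np.nan)
               for i, lv in enumerate(vc_levels)}
    rows = [("site", site_var)] + [(lv, v) for lv, v in vc_vars.items()]
    rows.append(("residual", scale))
    total = sum(v for _, v in rows)
    random = pd.DataFrame(
        [(g, v, np.sqrt(max(v, 0.0)), 100.0 * v / total) for g, v in rows],
        columns=["group", "variance", "sd", "pct_of_total"])
    res = ModelResult(name=name, family="gaussian", link="identity",
                      fixed=fixed, random=random, loglik=float(fit.llf),
                      aicc=aicc(float(fit.llf), k, len(data)),
                      n=len(data), k_params=k, extra=extra or {})
    return res, fit


def _lmm_with_treatment_lrt(df, response, fe_full, fe_reduced, vc_levels,
                            name, extra=None) -> ModelResult:
    full, _ = _fit_lmm(df, response, fe_full, vc_levels, name, extra)
    red, _ = _fit_lmm(df, response, fe_reduced, vc_levels, name + " (null)", extra)
    chi2, dfree, p = lrt(full, red)
    full.lrt_treatment = {"chi2": chi2, "df": dfree, "p": p}
    return full


def fit_trajectory_models(metrics: pd.DataFrame, dropna: bool = True
                          ) -> dict[str, ModelResult]:
    """Fit the per-trajectory response models.

    ``metrics`` needs the flight-metrics columns plus treatment, block
    (order 1..12), night and site labels. Speed and distance are Gaussian
    LMMs on the identity scale; height is Box-Cox transformed (lambda by
    profile ML, reported); length is log transformed; the tortuosity value
    is a beta GLMM with cloglog link on the (0, 1) domain, with values
    outside (0, 1) excluded (count logged). Fixed effects are treatment,
    block order, distance and treatment x distance (the distance model uses
    treatment and block order only); random intercepts are block nested in
    night nested in site throughout.
    """
    df = metrics.copy()
    df["block_order"] = (df["block"].astype(float) - 6.5) / 5.5
    df["treatment"] = pd.Categorical(df["treatment"],
                                     categories=["control", "deterrent"])
    # centred so the treatment main effect is read at the mean distance
    dist = df["distance_from_deterrent_m"].astype(float)
    df["distance"] = dist - dist.mean()
    out: dict[str, ModelResult] = {}

    fe_full = ["treatment", "block_order", "distance", "treatment:distance"]
    fe_null = ["block_order", "distance"]

    df["speed"] = df["mean_speed_ms"]
    out["speed"] = _lmm_with_treatment_lrt(
        df, "speed", fe_full, fe_null, ["night", "block"], "speed")

    out["distance"] = _lmm_with_treatment_lrt(
        df, "distance", ["treatment", "block_order"], ["block_order"],
        ["night", "block"], "distance")

    h = df["mean_height_m"].astype(float)
    shift = float(max(0.0, -(h.min()) + 0.1))
    bc, lam = sps.boxcox(h + shift)
    df["height_bc"] = bc
    out["height"] = _lmm_with_treatment_lrt(
        df, "height_bc", fe_full, fe_null, ["night", "block"], "height",
        extra={"boxcox_lambda": float(lam), "boxcox_shift": shift})

    df["log_length"] = np.log(df["total_length_m"].astype(float))
    out["length"] = _lmm_with_treatment_lrt(
        df, "log_length", fe_full, fe_null, ["night", "block"], "length")

    tort = df["tortuosity"].astype(float)
    ok = (tort > 0.0) & (tort < 1.0) & np.isfinite(tort)
    n_excl = int((~ok).sum())
    if n_excl:
        log.info("tortuosity model: excluded %d value(s) outside (0, 1)", n_excl)
    sub = df[ok]
    X, names = _design(sub, fe_full)
    Xr, names_r = _design(sub, fe_null)
    groups = _nested_groups(sub)
    yb = sub["tortuosity"].to_numpy(dtype=float)
    fam = BetaCloglog()
    full = fit_glmm(yb, X, groups, fam, fe_names=names)
    red = fit_glmm(yb, Xr, groups, fam, fe_names=names_r)
    chi2, dfree, p = lrt(full, red)
    out["tortuosity"] = _glmm_to_result(
        "tortuosity", full, lrt_dict={"chi2": chi2, "df": dfree, "p": p},
        extra={"n_excluded": n_excl})
    return out


def fit_call_param_model(calls: pd.DataFrame, response: str,
                         m_tests: int = N_CALL_RESPONSES) -> ModelResult:
    """Gaussian LMM for one call parameter.

    Fixed effects: deterrent treatment, time-block order and number of bats;
    random intercepts site / night / block pair / time block / call sequence
    (fully nested). The five-level nesting routinely drives variance
    components to the boundary, so this model uses the package's exact-ML
    Gaussian mixed model rather than the dedicated LMM routine. Both the raw
    and the Bonferroni-adjusted treatment p-value (m = 6 responses measured
    on the same calls) are attached.
    """
    from .glmm import Gaussian

    for arm in ("control", "deterrent"):
        n_arm = calls.loc[calls["treatment"] == arm, "sequence"].nunique()
        if n_arm < 2:
            raise SparseDataError(f"need >= 2 passes in the {arm} arm")
    df = calls.copy()
    y = df[response].to_numpy(dtype=float)
    treat = (df["treatment"].to_numpy() == "deterrent").astype(float)
    order = df["block_pair"].astype("category").cat.codes.to_numpy(dtype=float)
    nbats = df["n_bats"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df)), treat, order, nbats])
    names = ["intercept", "treatment[deterrent]", "block_order", "n_bats"]
    groups = _nested_groups(df, ("site", "night", "block_pair", "time_block",
                                 "sequence"))
    full = fit_glmm(y, X, groups, Gaussian(), fe_names=names)
    red = fit_glmm(y, X[:, [0, 2, 3]], groups, Gaussian(),
                   fe_names=[names[0]] + names[2:])
    chi2, dfree, p = lrt(full, red)
    res = _glmm_to_result(f"call:{response}", full,
                          lrt_dict={"chi2": chi2, "df": dfree, "p": p},
                          extra={"m_tests": m_tests})
    res.lrt_treatment["p_adjusted"] = bonferroni(p, m_tests)
    return res


# ---------------------------------------------------------------------------
# Descriptive outputs
# ---------------------------------------------------------------------------

def percent_reduction(blocks: pd.DataFrame, species_groups=None,
                      event_types=None, model: ModelResult | None = None
                      ) -> dict[str, float | None]:
    """Percent reduction of treated relative to control totals.

    Returns the raw-total figure 100 (1 - treated/control) (negative for an
    increase) and, when a fitted count model is supplied, the model-based
    figure 100 (1 - exp(beta_treatment)) alongside.
    """
    sub = blocks
    if species_groups is not None:
        sub = sub[sub["species_group"].isin(list(species_groups))]
    if event_types is not None:
        sub = sub[sub["event_type"].isin(list(event_types))]
    totals = sub.groupby("treatment")["count"].sum()
    if "control" not in totals or "deterrent" not in totals:
        raise ValueError("need both control and deterrent blocks")
    if totals["control"] == 0:
        raise ValueError("no control events; reduction undefined")
    raw = 100.0 * (1.0 - totals["deterrent"] / totals["control"])
    model_based = None
    if model is not None:
        model_based = 100.0 * (1.0 - float(np.exp(model.coef("treatment[deterrent]"))))
    return {"raw_pct": float(raw), "model_pct": model_based,
            "control_total": int(totals["control"]),
            "deterrent_total": int(totals["deterrent"])}


def composition_table(blocks: pd.DataFrame, event_type: str = "pass"
                      ) -> tuple[pd.DataFrame, dict]:
    """Per-species totals, percentages (2 d.p.) and per-night means.

    The per-night mean is the grand total divided by the number of nights.
    Percentages sum to 100 up to rounding.
    """
    sub = blocks[blocks["event_type"] == event_type]
    totals = (sub.groupby("species_group")["count"].sum()
              .sort_values(ascending=False))
    grand = int(totals.sum())
    n_nights = int(sub.groupby(["site", "night"]).ngroups) or 1
    table = pd.DataFrame({
        "species_group": totals.index,
        "total": totals.values,
        "percent": np.round(100.0 * totals.values / grand, 2) if grand else 0.0,
    })
    summary = {"grand_total": grand, "n_nights": n_nights,
               "per_night_mean": grand / n_nights}
    return table.reset_index(drop=True), summary
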