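"""Sensitivity analysis: crude/adjusted RORs and interaction models.

The three study drugs are pooled into one case-level dataset; for one
drug and one SOC outcome, logistic regression of the outcome on the
exposure indicator gives the crude ROR (Model 1, exactly the collapsed
2x2 odds ratio), adding sex and a binary age group gives the adjusted
ROR (Model 2), and exposure x factor product terms give interaction
RORs for sex, age group and US vs non-US reporting country (Models
3-5). Cases missing sex, age or country are excluded; age splits at
the pooled median; reference levels are male, age below the median and
non-US.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .cases import AnalysisSet
from .meddra import TermMaps, reactions_at_level
from .onset import is_us

logger = logging.getLogger(__name__)

Z95 = 1.96
MAX_ITER = 100
TOL = 1e-10
SEPARATION_BOUND = 15.0  # |coefficient| beyond this flags separation

INTERACTION_FACTORS = ("sex", "age_group", "country_us")


class ConvergenceError(RuntimeError):
    pass


@dataclass
class LogisticFit:
    """IRLS maximum-likelihood logistic fit with Wald intervals."""

    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame  # columns lo, hi
    deviance: float
    deviance_path: list[float]
    n_iter: int
    converged: bool
    separation: list[str] = field(default_factory=list)

    def odds_ratio(self, name: str) -> tuple[float, float, float]:
        lo, hi = self.conf_int.loc[name, "lo"], self.conf_int.loc[name, "hi"]
        with np.errstate(over="ignore"):  # separated fits: bound -> inf
            return (float(np.exp(self.params[name])),
                    float(np.exp(lo)), float(np.exp(hi)))


def _deviance(y: np.ndarray, eta: np.ndarray) -> float:
    # -2 log-likelihood on the linear-predictor scale; logaddexp keeps
    # extreme eta (separation) finite and warning-free
    return float(-2.0 * np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    add_intercept: bool = True,
    max_iter: int = MAX_ITER,
    tol: float = TOL,
) -> LogisticFit:
    """Logistic regression by iteratively reweighted least squares.

    Newton steps with step-halving, so the deviance decreases
    monotonically; converged when the largest coefficient change drops
    below ``tol``. Coefficients diverging past ``SEPARATION_BOUND`` are
    flagged (quasi-)separated rather than silently penalized;
    non-convergence raises with diagnostics.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        names = [f"x{i}" for i in range(Xm.shape[1])]
    if add_intercept:
        Xm = np.column_stack([np.ones(len(Xm)), Xm])
        names = ["intercept"] + names
        # constant covariates are aliased with the intercept: drop them
        keep = [0] + [j for j in range(1, Xm.shape[1]) if np.ptp(Xm[:, j]) > 0]
        dropped = [names[j] for j in range(Xm.shape[1]) if j not in keep]
        if dropped:
            logger.warning("dropping constant column(s) %s", dropped)
            Xm = Xm[:, keep]
            names = [names[j] for j in keep]
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome has a single class")

    n, p = Xm.shape
    beta = np.zeros(p)
    dev = _deviance(y, np.zeros(n))  # deviance at the zero start
    path = [dev]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = Xm @ beta
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        WX = Xm * w[:, None]
        try:
            step_target = np.linalg.solve(Xm.T @ WX, Xm.T @ (w * z))
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        direction = step_target - beta
        if np.max(np.abs(direction)) < tol:
            converged = True
            break
        # step-halving keeps the deviance monotone non-increasing
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * direction
            dev_new = _deviance(y, Xm @ cand)
            if dev_new <= dev + 1e-8:
                break
            scale /= 2.0
        else:  # pragma: no cover - pathological
            raise ConvergenceError("step-halving failed to reduce deviance")
        delta = np.max(np.abs(cand - beta))
        beta = cand
        dev = dev_new
        path.append(dev)
        if delta < tol:
            converged = True
            break
    separated = [names[j] for j in range(p) if abs(beta[j]) > SEPARATION_BOUND]
    if not converged and not separated:
        raise ConvergenceError(
            f"no convergence in {max_iter} iterations "
            f"(last deviance {dev:.6g}, max |beta| {np.max(np.abs(beta)):.3g})"
        )
    if separated:
        logger.warning("separation suspected for %s", separated)

    eta = Xm @ beta
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    cov = np.linalg.inv(Xm.T @ (Xm * w[:, None]))
    se = np.sqrt(np.diag(cov))
    params = pd.Series(beta, index=names)
    bse = pd.Series(se, index=names)
    ci = pd.DataFrame(
        {"lo": beta - Z95 * se, "hi": beta + Z95 * se}, index=names
    )
    return LogisticFit(
        params=params, bse=bse, conf_int=ci, deviance=dev,
        deviance_path=path, n_iter=n_iter, converged=converged,
        separation=separated,
    )


def prepare_rows(
    aset: AnalysisSet,
    soc_list: list[str],
    maps: TermMaps,
    drugs: list[str] | None = None,
) -> tuple[pd.DataFrame, float, dict[str, int]]:
    """Pooled case-level design table for the sensitivity models.

    One row per case exposed to exactly one study drug (covariates come
    from the case's retained, deduplicated report); outcomes are
    indicators for each SOC in ``soc_list``; rows missing sex, age or
    country are excluded and counted. Age dichotomizes at the pooled
    median age (computed over pooled cases with a known age).

    Returns (rows, pooled_median_age, exclusion_counts).
    """
    drugs = drugs or aset.drug_labels
    pooled = []
    excl = {"multi_or_no_drug": 0, "missing_sex": 0, "missing_age": 0,
            "missing_country": 0}
    for rep in aset.reports:
        exposed = [d for d in drugs if aset.exposure[rep.primaryid][d]]
        if len(exposed) != 1:
            if exposed:
                excl["multi_or_no_drug"] += 1
            continue
        pooled.append((rep, exposed[0]))

    ages = [r.age_years for r, _ in pooled if r.age_years is not None]
    if not ages:
        raise ValueError("no cases with known age in the pooled dataset")
    median_age = float(np.median(ages))

    rows = []
    for rep, drug in pooled:
        if rep.sex not in ("M", "F"):
            excl["missing_sex"] += 1
            continue
        if rep.age_years is None:
            excl["missing_age"] += 1
            continue
        us = is_us(rep.country)
        if us is None:
            excl["missing_country"] += 1
            continue
        socs = reactions_at_level(rep, "SOC", maps)
        socs_l = {s.lower() for s in socs}
        row = {
            "caseid": rep.caseid,
            "drug": drug,
            "sex": 1 if rep.sex == "F" else 0,
            "age_group": 1 if rep.age_years >= median_age else 0,
            "country_us": 1 if us else 0,
        }
        for soc in soc_list:
            row[f"outcome_{soc}"] = 1 if soc.lower() in socs_l else 0
        rows.append(row)
    if not rows:
        raise ValueError("no cases left after missing-data exclusions")
    df = pd.DataFrame(rows)
    logger.info(
        "prepare_rows: %d cases retained, exclusions %s, pooled median age %.1f",
        len(df), excl, median_age,
    )
    return df, median_age, excl


def _design(rows: pd.DataFrame, drug: str, terms: list[str]) -> pd.DataFrame:
    X = pd.DataFrame(index=rows.index)
    X["exposure"] = (rows["drug"] == drug).astype(float)
    for t in terms:
        if t == "exposure":
            continue
        if t.startswith("exposure:"):
            X[t] = X["exposure"] * rows[t.split(":", 1)[1]].astype(float)
        else:
            X[t] = rows[t].astype(float)
    return X


def adjusted_ror(
    rows: pd.DataFrame, drug: str, soc: str, model: int = 2
) -> tuple[tuple[float, float, float], LogisticFit]:
    """Model 1 (crude) or Model 2 (sex- and age-adjusted) ROR.

    The exposure contrast is this drug versus the other pooled drugs.
    Returns ((ror, lo, hi), fit).
    """
    if model == 1:
        terms = ["exposure"]
    elif model == 2:
        terms = ["exposure", "sex", "age_group"]
    else:
        raise ValueError("model must be 1 or 2")
    y = rows[f"outcome_{soc}"].to_numpy()
    fit = fit_logistic(_design(rows, drug, terms), y)
    return fit.odds_ratio("exposure"), fit


def interaction_ror(
    rows: pd.DataFrame, drug: str, soc: str, factor: str
) -> tuple[tuple[float, float, float], LogisticFit]:
    """Exposure x factor interaction ROR (Models 3-5).

    ``factor`` is sex, age_group or country_us; the returned odds ratio
    multiplies the exposure OR when moving from the reference stratum
    (male / below-median age / non-US) to the other. In the saturated
    model it equals the ratio of stratum-specific odds ratios. A factor
    constant across rows has no estimable interaction and raises.
    """
    if factor not in INTERACTION_FACTORS:
        raise ValueError(f"factor must be one of {INTERACTION_FACTORS}")
    if rows[factor].nunique() < 2:
        raise ValueError(f"factor {factor!r} is constant; interaction not estimable")
    terms = ["exposure", factor, f"exposure:{factor}"]
    y = rows[f"outcome_{soc}"].to_numpy()
    fit = fit_logistic(_design(rows, drug, terms), y)
    return fit.odds_ratio(f"exposure:{factor}"), fit


def sensitivity_table(
    rows: pd.DataFrame, drugs: list[str], soc_list: list[str]
) -> pd.DataFrame:
    """Model 1-5 RORs for every drug x SOC, Table-3 layout.

    Columns: drug, soc, model, ror, lo, hi, flagged (separation).
    """
    out = []
    for drug in drugs:
        for soc in soc_list:
            for model in (1, 2):
                (ror, lo, hi), fit = adjusted_ror(rows, drug, soc, model=model)
                out.append((drug, soc, f"model{model}", ror, lo, hi,
                            bool(fit.separation)))
            for i, factor in enumerate(INTERACTION_FACTORS, start=3):
                try:
                    (ror, lo, hi), fit = interaction_ror(rows, drug, soc, factor)
                    flagged = bool(fit.separation)
                except (ValueError, ConvergenceError) as exc:
                    logger.warning("model%d %s/%s: %s", i, drug, soc, exc)
                    ror = lo = hi = float("nan")
                    flagged = True
                out.append((drug, soc, f"model{i}", ror, lo, hi, flagged))
    return pd.DataFrame(
        out, columns=["drug", "soc", "model", "ror", "lo", "hi", "flagged"]
    )
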