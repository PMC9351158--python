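"""Empirical-stage pipeline: descriptives and the four-model comparison.

Given any table with a count outcome (e.g. hospital length of stay) and
a mix of continuous and categorical covariates, this module produces a
descriptive summary, fits Poisson, NB, ZIP and ZINB regressions with
identical count-part covariates (and, for the zero-inflated models,
the same covariates in the logistic zero part), and assembles a report
of coefficients, standard errors, p-values, Pearson dispersion and
AIC/BIC ranked by fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import FitResult, ModelSpec, fit, pearson_dispersion
from .likelihoods import FAMILIES

#: conventional reference levels for the hospital-admissions covariates
DEFAULT_REFERENCE_LEVELS = {
    "sex": "male",
    "insurance": "self-pay",
    "admission_type": "urgent",
}

__all__ = ["ComparisonReport", "describe", "compare_models", "DEFAULT_REFERENCE_LEVELS"]


def describe(table: pd.DataFrame, outcome: str = "los") -> dict:
    """Descriptive summary of the outcome and categorical covariates.

    Flags variance >> mean of the count outcome as an overdispersion
    signal (the key diagnostic against the Poisson assumption).
    """
    df = pd.DataFrame(table)
    y = df[outcome].to_numpy()
    bad = np.where((y < 0) | (y != np.floor(y)))[0]
    if bad.size:
        raise ValueError(f"outcome must be nonnegative integers; offending rows: {bad[:10].tolist()}")
    y = y.astype(float)
    out = {
        "n": int(len(y)),
        "mean": float(np.mean(y)),
        "variance": float(np.var(y, ddof=1)),
        "sd": float(np.std(y, ddof=1)),
        "zero_fraction": float(np.mean(y == 0)),
        "min": int(y.min()),
        "max": int(y.max()),
    }
    out["overdispersed"] = out["variance"] > out["mean"]
    cats = {}
    for col in df.columns:
        if col == outcome:
            continue
        if df[col].dtype == object or isinstance(df[col].dtype, pd.CategoricalDtype):
            counts = df[col].value_counts()
            cats[col] = {
                level: {"n": int(cnt), "percent": 100.0 * cnt / len(df)}
                for level, cnt in counts.items()
            }
    out["categories"] = cats
    return out


@dataclass
class ComparisonReport:
    """Four-model comparison in the style of a side-by-side findings table."""

    outcome: str
    fits: dict  # family -> FitResult
    coefficients: pd.DataFrame  # long: model, term, estimate, se, z, p, significant
    dispersion: dict  # family -> Pearson dispersion (NaN when non-converged)
    descriptives: dict
    alpha_level: float = 0.05

    @property
    def aic(self) -> dict:
        return {fam: f.aic for fam, f in self.fits.items()}

    @property
    def bic(self) -> dict:
        return {fam: f.bic for fam, f in self.fits.items()}

    def ranking(self, criterion: str = "aic") -> list:
        """Model families ordered best (smallest criterion) first."""
        vals = self.aic if criterion == "aic" else self.bic
        ordered = sorted(
            (fam for fam in vals if np.isfinite(vals[fam])), key=lambda f: vals[f]
        )
        return ordered + [f for f in vals if not np.isfinite(vals[f])]

    def to_csv(self, path) -> None:
        self.coefficients.to_csv(path, index=False)

    def render_text(self) -> str:
        """Human-readable side-by-side rendering of the comparison."""
        lines = [f"Comparison of count regression models for '{self.outcome}'", ""]
        d = self.descriptives
        lines.append(
            f"n = {d['n']}, mean = {d['mean']:.2f}, variance = {d['variance']:.2f}, "
            f"zeros = {100 * d['zero_fraction']:.1f}%"
            + ("  [variance > mean: overdispersion signal]" if d["overdispersed"] else "")
        )
        lines.append("")
        for part in ("count", "zero"):
            sub = self.coefficients[self.coefficients.part == part]
            if sub.empty:
                continue
            lines.append(f"--- {part} part ---")
            for term, tdf in sub.groupby("term", sort=False):
                cells = [
                    f"{row.model}: {row.estimate:.4g} ({row.se:.4g}) p={row.p:.4g}"
                    for row in tdf.itertuples()
                ]
                lines.append(f"{term:28s} " + " | ".join(cells))
            lines.append("")
        lines.append("model    converged  Pearson-disp       AIC       BIC")
        for fam, f in self.fits.items():
            disp = self.dispersion.get(fam, np.nan)
            lines.append(
                f"{fam:8s} {str(f.converged):9s} {disp:13.4f} {f.aic:9.1f} {f.bic:9.1f}"
            )
        lines.append("")
        lines.append(f"best by AIC: {self.ranking('aic')[0]}; best by BIC: {self.ranking('bic')[0]}")
        return "\n".join(lines)


def _encode(df: pd.DataFrame, covariates, reference_levels) -> tuple[pd.DataFrame, list]:
    """Dummy-encode categorical covariates against the reference levels."""
    refs = dict(DEFAULT_REFERENCE_LEVELS)
    refs.update(reference_levels or {})
    encoded = pd.DataFrame(index=df.index)
    terms = []
    for col in covariates:
        s = df[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(s.astype(str).unique())
            ref = refs.get(col)
            if ref is None or ref not in levels:
                ref = levels[0]
            for lev in levels:
                if lev == ref:
                    continue
                name = f"{col}_{lev}"
                encoded[name] = (s.astype(str) == lev).astype(float)
                terms.append(name)
        else:
            encoded[col] = s.astype(float)
            terms.append(col)
    return encoded, terms


def compare_models(
    table: pd.DataFrame,
    outcome: str,
    covariates,
    reference_levels: dict | None = None,
    families=FAMILIES,
    alpha_level: float = 0.05,
) -> ComparisonReport:
    """Fit all four families with identical covariates and assemble a report.

    Zero-inflated fits use the same predictors in the count and the
    logistic zero part.  Non-converged fits stay in the report flagged
    as such; boundary fits (e.g. separation in the zero part) are
    reported with their large standard errors as-is.
    """
    df = pd.DataFrame(table)
    covariates = list(covariates)
    encoded, terms = _encode(df, covariates, reference_levels)
    work = pd.concat([df[[outcome]].reset_index(drop=True), encoded.reset_index(drop=True)], axis=1)

    fits: dict[str, FitResult] = {}
    disp: dict[str, float] = {}
    rows = []
    for fam in families:
        spec = ModelSpec(
            family=fam,
            count_covariates=terms,
            zero_covariates=terms if fam in ("zip", "zinb") else "intercept_only",
        )
        res = fit(spec, work, outcome=outcome)
        fits[fam] = res
        disp[fam] = pearson_dispersion(res) if res.converged else float("nan")
        for i, name in enumerate(res.param_names):
            part = "zero" if name.startswith("zero_") else ("dispersion" if name == "alpha" else "count")
            term = name.split("_", 1)[1] if "_" in name else name
            se = res.se[i] if res.se is not None else np.nan
            z = res.z[i] if res.z is not None else np.nan
            p = res.p[i] if res.p is not None else np.nan
            rows.append(
                {
                    "model": fam,
                    "part": part,
                    "term": term,
                    "estimate": res.params[i],
                    "se": se,
                    "z": z,
                    "p": p,
                    "significant": bool(p < alpha_level) if np.isfinite(p) else False,
                    "converged": res.converged,
                }
            )
    coef = pd.DataFrame(rows)
    return ComparisonReport(
        outcome=outcome,
        fits=fits,
        coefficients=coef,
        dispersion=disp,
        descriptives=describe(df[[outcome] + covariates], outcome=outcome),
        alpha_level=alpha_level,
    )
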