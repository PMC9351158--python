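"""Per-replication and per-scenario performance metrics.

The study protocol: every replication records whether each fitted model
converged; AIC, BIC and the mean absolute error of the estimated
conditional mean are extracted for converged fits only, and scenario
summaries average them over the converged replications.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ReplicationRecord", "ScenarioSummary", "mae", "convergence_rate", "summarize"]


@dataclass(frozen=True)
class ReplicationRecord:
    """Outcome of fitting one model to one replication of one scenario."""

    scenario_id: str
    replication: int
    model: str
    converged: bool
    aic: float | None = None
    bic: float | None = None
    mae: float | None = None
    seed: int | None = None
    failure_reason: str | None = None

    def __post_init__(self):
        present = all(v is not None and np.isfinite(v) for v in (self.aic, self.bic, self.mae))
        if self.converged and not present:
            raise ValueError("converged records must carry finite aic, bic and mae")


@dataclass(frozen=True)
class ScenarioSummary:
    """One row of the study's result tables: scenario x model aggregates."""

    scenario_id: str
    model: str
    convergence_rate: float  # percent
    mean_aic: float | None
    mean_bic: float | None
    mean_mae: float | None
    n_converged: int
    replications: int
    se_aic: float | None = None
    se_bic: float | None = None
    se_mae: float | None = None


def mae(true_mean, predicted_mean) -> float:
    """Mean absolute error between true and fitted conditional means.

    `true_mean` is the data-generating process's conditional mean
    E(Y|x) (mu, or mu(1-phi) for the zero-inflated processes); pass the
    observed counts instead to get the mean absolute residual variant.
    """
    t = np.asarray(true_mean, dtype=float)
    f = np.asarray(predicted_mean, dtype=float)
    if t.shape != f.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {f.shape}")
    if t.size == 0:
        raise ValueError("need at least one observation")
    return float(np.mean(np.abs(t - f)))


def convergence_rate(records) -> float:
    """Percentage of records whose fit satisfied the convergence criterion."""
    records = list(records)
    if not records:
        raise ValueError("empty record list")
    return 100.0 * sum(r.converged for r in records) / len(records)


def _mean_se(values):
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return None, None
    se = float(np.std(values, ddof=1) / np.sqrt(values.size)) if values.size > 1 else 0.0
    return float(np.mean(values)), se


def summarize(records) -> ScenarioSummary:
    """Aggregate one scenario x model group of replication records.

    AIC/BIC/MAE means are computed over the converged replications only;
    the convergence rate uses all records.  Replication-level standard
    errors accompany each mean so Monte-Carlo uncertainty is explicit.
    """
    records = list(records)
    if not records:
        raise ValueError("empty record list")
    ids = {(r.scenario_id, r.model) for r in records}
    if len(ids) > 1:
        raise ValueError(f"records span multiple scenario x model groups: {sorted(ids)}")
    scenario_id, model = next(iter(ids))
    conv = [r for r in records if r.converged]
    mean_aic, se_aic = _mean_se([r.aic for r in conv])
    mean_bic, se_bic = _mean_se([r.bic for r in conv])
    mean_mae, se_mae = _mean_se([r.mae for r in conv])
    return ScenarioSummary(
        scenario_id=scenario_id,
        model=model,
        convergence_rate=100.0 * len(conv) / len(records),
        mean_aic=mean_aic,
        mean_bic=mean_bic,
        mean_mae=mean_mae,
        n_converged=len(conv),
        replications=len(records),
        se_aic=se_aic,
        se_bic=se_bic,
        se_mae=se_mae,
    )
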