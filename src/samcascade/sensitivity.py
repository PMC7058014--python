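"""Local normalized sensitivity of total steady-state HAM mRNA.

For a parameter p and the model output m (total HAM mRNA summed over
all cells at steady state), the normalized sensitivity is

    S = (dm / dp) * (p / m),

estimated with a one-sided forward difference at a +1 % perturbation:
the parameter is increased to 1.01 p, the simulation repeated, and
S = (m' - m) / (0.01 m).  S is the elasticity of the output: S = 1
means m scales proportionally with p.

To keep the finite difference free of stopping-time noise, the
perturbed run is integrated for exactly the duration the base run
needed to converge (same fixed Euler steps) rather than to its own
stopping criterion.  This makes structurally exact sensitivities exact
in floating point as well: S(k_hrp) = 1 because the HAM mRNA equation
is linear in k_hrp and miR171 is independent of it, and S = 0 for
every parameter downstream of HAM mRNA (the protein and reporter
rates), which cannot feed back.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    SEARCH_KEYS,
    ModelError,
    ModelParameters,
    SimulationConfig,
    SimulationResult,
    integrate_euler,
    total_ham_mrna,
)
from .template import CellTemplate, MLpField, make_ml1p_wildtype


class SensitivityError(ValueError):
    pass


@dataclass(frozen=True)
class SensitivityReport:
    """Per-(parameter, ensemble member) normalized sensitivities.

    ``values`` is a DataFrame with one row per ensemble member and one
    column per parameter key (NaN marks a failed member).  ``median``
    and ``iqr`` summarise the signed values per key, ``abs_median`` the
    magnitudes; ``ranked_keys`` orders the keys by decreasing median |S|.
    """

    values: pd.DataFrame
    delta_frac: float
    output: str = "total_ham_mrna"
    failures: dict[int, str] = field(default_factory=dict)

    @property
    def median(self) -> pd.Series:
        return self.values.median()

    @property
    def abs_median(self) -> pd.Series:
        return self.values.abs().median()

    @property
    def iqr(self) -> pd.Series:
        return self.values.quantile(0.75) - self.values.quantile(0.25)

    @property
    def ranked_keys(self) -> list[str]:
        return list(self.abs_median.sort_values(ascending=False).index)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"median": self.median, "abs_median": self.abs_median, "iqr": self.iqr}
        )


def normalized_sensitivity(
    params: ModelParameters,
    key: str,
    template: CellTemplate,
    ml1p: MLpField | None = None,
    delta_frac: float = 0.01,
    config: SimulationConfig | None = None,
    base_result: SimulationResult | None = None,
) -> float:
    """Normalized sensitivity of total steady-state HAM mRNA to one parameter.

    ``base_result`` may supply an already-computed base simulation (it
    must match ``params``); otherwise the base run is performed here.
    Raises on non-convergence of the base run or a non-positive output.
    """
    if delta_frac <= 0:
        raise SensitivityError("delta_frac must be positive")
    config = config or SimulationConfig()
    ml1p = ml1p if ml1p is not None else make_ml1p_wildtype(template)
    if base_result is None:
        base_result = integrate_euler(ml1p, params, template, config)
    if not base_result.converged:
        raise SensitivityError("base simulation did not converge")
    m = total_ham_mrna(base_result.final_state)
    if m <= 0:
        raise SensitivityError("total HAM mRNA output is not positive")

    p = getattr(params, key)  # raises AttributeError for unknown keys
    perturbed = params.scale(key, 1.0 + delta_frac)
    # fixed-duration rerun over the base run's steps: tol 0 disables the
    # early stop so both trajectories take identical time points
    fixed = SimulationConfig(
        dt=config.dt,
        t_max=base_result.t_final,
        steady_tol=0.0,
        ceiling=config.ceiling,
        allow_unstable=config.allow_unstable,
    )
    import warnings

    with warnings.catch_warnings():
        # the fixed-duration rerun never triggers the early-stop criterion,
        # so the integrator's "not converged" warning is expected noise here
        warnings.simplefilter("ignore", UserWarning)
        pert_result = integrate_euler(ml1p, perturbed, template, fixed)
    m_pert = total_ham_mrna(pert_result.final_state)
    return (m_pert - m) / (delta_frac * m)


def sensitivity_profile(
    ensemble: list[ModelParameters],
    keys: tuple[str, ...] = SEARCH_KEYS,
    template: CellTemplate | None = None,
    ml1p: MLpField | None = None,
    delta_frac: float = 0.01,
    config: SimulationConfig | None = None,
) -> SensitivityReport:
    """Sensitivities of every key for every ensemble member.

    One base simulation per member is shared across its six perturbed
    runs.  Members whose base run fails are recorded in
    ``report.failures`` and contribute NaN rows; the sweep never aborts.
    """
    if not ensemble:
        raise SensitivityError("ensemble must be non-empty")
    if template is None:
        raise SensitivityError("a template is required")
    config = config or SimulationConfig()
    ml1p = ml1p if ml1p is not None else make_ml1p_wildtype(template)

    rows = []
    failures: dict[int, str] = {}
    for idx, params in enumerate(ensemble):
        row = {k: np.nan for k in keys}
        try:
            base = integrate_euler(ml1p, params, template, config)
            for key in keys:
                row[key] = normalized_sensitivity(
                    params, key, template, ml1p, delta_frac, config, base_result=base
                )
        except (ModelError, SensitivityError, Warning) as exc:
            failures[idx] = str(exc)
        rows.append(row)
    values = pd.DataFrame(rows, columns=list(keys))
    return SensitivityReport(values=values, delta_frac=delta_frac, failures=failures)


def write_sensitivity_csv(report: SensitivityReport, path, summary_path=None) -> None:
    long = report.values.reset_index(names="set_id").melt(
        id_vars="set_id", var_name="parameter", value_name="sensitivity"
    )
    long.to_csv(path, index=False)
    if summary_path is not None:
        report.summary_frame().rename_axis("parameter").to_csv(summary_path)
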