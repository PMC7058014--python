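"""Parameter-space exploration: local one-at-a-time grid and QMC random search.

Two complementary procedures probe how widely the wild-type HAM mRNA
gradient persists in parameter space:

* a local one-at-a-time (OAT) grid around a baseline — each of the six
  key parameters is scaled through 40-200 % of its baseline value at
  2 % intervals while the others stay fixed, giving 6 x 80 variants
  plus the baseline, 481 sets in total;
* an unbiased random search — a scrambled Sobol low-discrepancy
  sequence mapped log-uniformly onto the biologically motivated bounds
  (the five rate constants in 0.1-1, the rescaled miR171 diffusion
  constant in 0.001-0.1 area a.u./h).

Every candidate set is screened by simulating the wild-type input to
steady state and applying the gradient classifier; failures of single
sets are recorded, never fatal.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .classify import ClassificationError, GradientCriteria, PatternVerdict, classify_wt_gradient
from .model import (
    BASELINE,
    PARAM_NAMES,
    SEARCH_KEYS,
    ModelParameters,
    SimulationConfig,
    SimulationResult,
    StateField,
    _euler_batch,
    layer_means,
    stability_margin,
    total_ham_mrna,
)
from .template import CellTemplate, MLpField


class SearchError(ValueError):
    pass


#: Search bounds stated for the unbiased random exploration: production
#: and degradation of one agent balanced within 100-fold, hence all five
#: rates in [0.1, 1]; miRNA movement between SAM cells is limited, hence
#: D_mir171 in [0.001, 0.1] area a.u./h.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "k_mirp": (0.1, 1.0),
    "k_mirn": (0.1, 1.0),
    "k_hrp": (0.1, 1.0),
    "k_hrnm": (0.1, 1.0),
    "k_hrnh": (0.1, 1.0),
    "D_mir171": (0.001, 0.1),
}


@dataclass(frozen=True)
class SearchSpace:
    """Per-parameter bounds for the random search (log-uniform by default)."""

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    scale: str = "log"

    def __post_init__(self):
        if self.scale not in ("log", "linear"):
            raise SearchError("scale must be 'log' or 'linear'")
        for key, (lo, hi) in self.bounds.items():
            if key not in PARAM_NAMES:
                raise SearchError(f"unknown parameter {key!r}")
            if not 0 < lo < hi:
                raise SearchError(f"bounds for {key} must satisfy 0 < low < high")

    @property
    def keys(self) -> tuple[str, ...]:
        return tuple(self.bounds)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"scale": self.scale, "bounds": self.bounds}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SearchSpace":
        doc = json.loads(Path(path).read_text())
        return cls(
            bounds={k: tuple(v) for k, v in doc["bounds"].items()},
            scale=doc.get("scale", "log"),
        )


@dataclass(frozen=True)
class ScreenRecord:
    """Outcome of screening one parameter set."""

    set_id: int
    params: ModelParameters
    converged: bool
    passed: bool
    verdict: PatternVerdict | None
    layer_means: dict[str, float] | None
    total_ham_mrna: float | None
    error: str | None = None


# ---------------------------------------------------------------------------
# set generation
# ---------------------------------------------------------------------------

def grid_oat(
    baseline: ModelParameters = BASELINE,
    lo_frac: float = 0.40,
    hi_frac: float = 2.00,
    step_frac: float = 0.02,
    keys: tuple[str, ...] = SEARCH_KEYS,
) -> list[ModelParameters]:
    """One-at-a-time grid: scale each key through [lo_frac, hi_frac] in steps.

    The baseline (every multiplier 1.0) appears first, followed by the
    variants in key order and ascending multiplier; exact duplicates of
    already-emitted sets (notably the baseline at multiplier 1.0) are
    dropped, so the default 6-key, 40-200 %, 2 %-step grid has
    6 x 80 + 1 = 481 unique sets.
    """
    if not lo_frac <= 1.0 <= hi_frac:
        raise SearchError("multiplier range must bracket 1.0")
    if step_frac <= 0:
        raise SearchError("step_frac must be positive")
    span = hi_frac - lo_frac
    n_steps = span / step_frac
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise SearchError(
            f"step {step_frac} does not tile the interval [{lo_frac}, {hi_frac}]"
        )
    multipliers = lo_frac + step_frac * np.arange(round(n_steps) + 1)
    for key in keys:
        if key not in PARAM_NAMES:
            raise SearchError(f"unknown parameter {key!r}")

    sets: list[ModelParameters] = [baseline]
    seen = {tuple(baseline.as_array())}
    for key in keys:
        for mult in multipliers:
            candidate = baseline.scale(key, float(mult))
            sig = tuple(candidate.as_array())
            if sig in seen:
                continue
            seen.add(sig)
            sets.append(candidate)
    return sets


def random_search_qmc(
    space: SearchSpace | None = None,
    n: int = 20000,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw ``n`` parameter sets from a scrambled Sobol sequence.

    Points in the unit cube are mapped per parameter by
    ``low * (high / low) ** u`` (uniform on the log scale) or affinely
    for a linear space.  Deterministic for a given seed; every draw lies
    strictly within its bounds.
    """
    space = space or SearchSpace()
    if n < 1:
        raise SearchError("n must be at least 1")
    sampler = qmc.Sobol(d=len(space.keys), scramble=True, seed=int(seed))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # non-power-of-two draw counts
        u = sampler.random(n)
    cols = {}
    for k, key in enumerate(space.keys):
        lo, hi = space.bounds[key]
        if space.scale == "log":
            cols[key] = lo * (hi / lo) ** u[:, k]
        else:
            cols[key] = lo + (hi - lo) * u[:, k]
    return pd.DataFrame(cols)


def draws_to_parameter_sets(
    draws: pd.DataFrame, base: ModelParameters = BASELINE
) -> list[ModelParameters]:
    """Complete sampled key subsets into full parameter sets around ``base``."""
    return [
        base.replace(**{k: float(row[k]) for k in draws.columns})
        for _, row in draws.iterrows()
    ]


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def screen(
    sets: list[ModelParameters],
    template: CellTemplate,
    ml1p: MLpField,
    criteria: GradientCriteria | None = None,
    config: SimulationConfig | None = None,
    batch_size: int = 128,
) -> list[ScreenRecord]:
    """Simulate and classify every parameter set against one input field.

    A pure map: one record per set, in input order, independent of the
    internal batching.  Sets that violate the Euler stability guard or
    diverge are recorded as failed non-hits rather than aborting the
    sweep; unconverged runs are likewise non-hits, flagged via
    ``converged``.
    """
    criteria = criteria or GradientCriteria()
    config = config or SimulationConfig()
    n = template.n_cells
    if len(ml1p.values) != n:
        raise SearchError("input field length does not match the template")

    records: list[ScreenRecord | None] = [None] * len(sets)
    param_mat = np.array([p.as_array() for p in sets]) if sets else np.empty((0, 12))
    max_deg = float(template.degrees().max(initial=0.0))
    margins = (
        stability_margin(ml1p.values[None, :], param_mat, max_deg, config.dt)
        if sets else np.empty(0)
    )
    stable_idx = [i for i in range(len(sets)) if margins[i] < 1.0 or config.allow_unstable]
    stable_set = set(stable_idx)
    for i in range(len(sets)):
        if i not in stable_set:
            records[i] = ScreenRecord(
                set_id=i, params=sets[i], converged=False, passed=False,
                verdict=None, layer_means=None, total_ham_mrna=None,
                error="stability guard: dt too coarse for this set",
            )

    ml1p_row = ml1p.values[None, :]
    for start in range(0, len(stable_idx), batch_size):
        chunk = stable_idx[start : start + batch_size]
        pmat = param_mat[chunk]
        finals, conv, div, t_fin, _ = _euler_batch(
            np.repeat(ml1p_row, len(chunk), axis=0), pmat, template, config
        )
        for j, i in enumerate(chunk):
            state = StateField.from_stack(finals[j])
            if div[j]:
                records[i] = ScreenRecord(
                    set_id=i, params=sets[i], converged=False, passed=False,
                    verdict=None, layer_means=None, total_ham_mrna=None,
                    error="diverged",
                )
                continue
            result = SimulationResult(
                final_state=state,
                converged=bool(conv[j]),
                t_final=float(t_fin[j]),
                provenance={
                    "params": sets[i].to_dict(),
                    "template_checksum": template.checksum(),
                    "ml1p_label": ml1p.label,
                },
            )
            means = layer_means(state, template, "ham_mrna")
            if not conv[j]:
                records[i] = ScreenRecord(
                    set_id=i, params=sets[i], converged=False, passed=False,
                    verdict=None, layer_means=means,
                    total_ham_mrna=total_ham_mrna(state),
                    error="not converged by t_max",
                )
                continue
            try:
                verdict = classify_wt_gradient(result, template, criteria)
                records[i] = ScreenRecord(
                    set_id=i, params=sets[i], converged=True,
                    passed=verdict.passed, verdict=verdict, layer_means=means,
                    total_ham_mrna=total_ham_mrna(state),
                )
            except ClassificationError as exc:  # pragma: no cover - defensive
                records[i] = ScreenRecord(
                    set_id=i, params=sets[i], converged=bool(conv[j]), passed=False,
                    verdict=None, layer_means=means,
                    total_ham_mrna=total_ham_mrna(state), error=str(exc),
                )
    return records  # type: ignore[return-value]


def screen_to_frame(records: list[ScreenRecord]) -> pd.DataFrame:
    """Tabulate screen records (one row per set) for CSV export."""
    rows = []
    for r in records:
        row = {"set_id": r.set_id, **r.params.to_dict(),
               "converged": r.converged, "passed": r.passed}
        if r.layer_means:
            for layer, v in r.layer_means.items():
                row[f"ham_mrna_mean_{layer}"] = v
        row["total_ham_mrna"] = r.total_ham_mrna
        row["error"] = r.error or ""
        rows.append(row)
    return pd.DataFrame(rows)


def hits(records: list[ScreenRecord]) -> list[ScreenRecord]:
    return [r for r in records if r.passed]
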