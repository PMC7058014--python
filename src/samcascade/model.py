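"""Reaction-diffusion dynamics of the L1 -> miR171 -> HAM cascade.

Five species per cell, all in arbitrary concentration units (a.u.):

* ``mir171`` — the mobile microRNA, produced in proportion to the local
  [ML1p] input, degraded at a constant rate, and exchanged between
  neighbouring cells through a graph-Laplacian diffusion term,
  d[miR171]/dt = k_mirp [ML1p] - k_mirn [miR171] + D_mir171 * Lap[miR171];
* ``ham_mrna`` — HAM mRNA, produced at a uniform rate k_hrp in every
  cell and degraded both independently of miR171 (k_hrnh) and in
  proportion to the local miR171 level (k_hrnm), the miRNA-guided
  cleavage term k_hrnm [HAMr][miR171];
* ``ham_protein`` — translated from HAM mRNA (k_hpp) and turned over
  (k_hpn);
* ``gfp_mrna`` / ``gfp_protein`` — an H2B-GFP transcriptional reporter
  of MIR171 promoter activity, driven by [ML1p] exactly like miR171
  production but immobile and with no feedback on the cascade.

The Laplacian is the discrete graph operator
``Lap f_i = sum_{n in neighbours(i)} (f_n - f_i)``; cells at the tissue
boundary simply have fewer neighbours, which realises a no-flux boundary
(total diffusing material is conserved).

Integration uses the explicit forward Euler scheme with a fine fixed
step (default 0.01 h) from an all-zero initial state until all time
derivatives fall below a steady-state tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix, eye as sparse_eye
from scipy.sparse.linalg import spsolve

from .template import LAYERS, CellTemplate, MLpField

SPECIES = ("mir171", "ham_mrna", "ham_protein", "gfp_mrna", "gfp_protein")

PARAM_NAMES = (
    "k_mirp", "k_mirn", "D_mir171",
    "k_hrp", "k_hrnm", "k_hrnh",
    "k_hpp", "k_hpn",
    "k_grp", "k_grn", "k_gpp", "k_gpn",
)

#: The six parameters of the miR171 / HAM mRNA equations that the
#: screening and sensitivity procedures focus on.
SEARCH_KEYS = ("k_mirp", "k_mirn", "k_hrp", "k_hrnm", "k_hrnh", "D_mir171")

_DEGRADATION = ("k_mirn", "k_hrnh", "k_hpn", "k_grn", "k_gpn")


class ModelError(ValueError):
    pass


class StabilityError(ModelError):
    """Forward-Euler step size too coarse for the given rates."""


class DivergenceError(ModelError):
    """A concentration became non-finite or exceeded the ceiling."""


@dataclass(frozen=True)
class ModelParameters:
    """The twelve rate constants of the cascade.

    Units: production rates driven by [ML1p] (k_mirp, k_grp) are
    a.u./h per a.u. of input; k_hrp is a.u./h; first-order rates
    (k_mirn, k_hrnh, k_hpp, k_hpn, k_grn, k_gpp, k_gpn) are 1/h;
    the miR171-guided degradation rate k_hrnm is 1/(a.u. h); D_mir171
    is the diffusion constant rescaled by cell size, area a.u./h.
    """

    k_mirp: float
    k_mirn: float
    D_mir171: float
    k_hrp: float
    k_hrnm: float
    k_hrnh: float
    k_hpp: float
    k_hpn: float
    k_grp: float
    k_grn: float
    k_gpp: float
    k_gpn: float

    def __post_init__(self):
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ModelError(f"parameter {name} must be finite and non-negative, got {v}")
        for name in _DEGRADATION:
            if getattr(self, name) <= 0:
                raise ModelError(f"degradation rate {name} must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values) -> "ModelParameters":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(PARAM_NAMES),):
            raise ModelError(f"expected {len(PARAM_NAMES)} values, got shape {values.shape}")
        return cls(**dict(zip(PARAM_NAMES, values)))

    def to_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in PARAM_NAMES}

    def replace(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)

    def scale(self, key: str, factor: float) -> "ModelParameters":
        if key not in PARAM_NAMES:
            raise ModelError(f"unknown parameter {key!r}")
        return replace(self, **{key: getattr(self, key) * factor})


#: Package default baseline.  The exact baseline of the original study is
#: not published; this set was selected from the documented search ranges
#: (five rates in 0.1-1, D_mir171 in 0.001-0.1) so that the wild-type
#: simulation on the standard 1216-cell dome passes the apical(low)-
#: basal(high) HAM-mRNA gradient classifier with the default criteria.
#: The four protein/reporter pairs, which do not shape the HAM mRNA
#: pattern, sit at the midpoint 0.5 of the rate range.
BASELINE = ModelParameters(
    k_mirp=0.9,
    k_mirn=0.1,
    D_mir171=0.005,
    k_hrp=0.5,
    k_hrnm=0.9,
    k_hrnh=0.1,
    k_hpp=0.5,
    k_hpn=0.5,
    k_grp=0.5,
    k_grn=0.5,
    k_gpp=0.5,
    k_gpn=0.5,
)


@dataclass(frozen=True)
class StateField:
    """Per-cell concentrations of the five dynamic species (a.u.)."""

    mir171: np.ndarray
    ham_mrna: np.ndarray
    ham_protein: np.ndarray
    gfp_mrna: np.ndarray
    gfp_protein: np.ndarray

    def __post_init__(self):
        n = len(np.asarray(self.mir171))
        for name in SPECIES:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ModelError("all species arrays must share one length")
            object.__setattr__(self, name, arr)

    @classmethod
    def zeros(cls, n_cells: int) -> "StateField":
        return cls(*(np.zeros(n_cells) for _ in SPECIES))

    @classmethod
    def from_stack(cls, stacked: np.ndarray) -> "StateField":
        return cls(*(stacked[k] for k in range(len(SPECIES))))

    def stack(self) -> np.ndarray:
        return np.stack([getattr(self, s) for s in SPECIES])

    @property
    def n_cells(self) -> int:
        return len(self.mir171)


class SingleCellSteadyState(NamedTuple):
    mir171: float
    ham_mrna: float
    ham_protein: float
    gfp_mrna: float
    gfp_protein: float


@dataclass(frozen=True)
class SimulationConfig:
    """Integrator settings.

    ``dt`` is the fixed Euler step in hours (default 0.01 h);
    ``steady_tol`` the steady-state criterion on the largest per-cell,
    per-species time derivative (a.u./h); ``t_max`` the hard time cap;
    ``ceiling`` the divergence guard on any concentration;
    ``record_every`` > 0 stores every that-many-th step of a single
    (non-batched) run.  ``allow_unstable`` overrides the explicit-Euler
    stability refusal.
    """

    dt: float = 0.01
    t_max: float = 2000.0
    steady_tol: float = 1e-8
    record_every: int = 0
    ceiling: float = 1e6
    allow_unstable: bool = False
    volume_scaled_diffusion: bool = False

    def __post_init__(self):
        if self.dt <= 0:
            raise ModelError("dt must be positive")
        if self.steady_tol < 0:
            raise ModelError("steady_tol must be non-negative")
        if self.t_max < self.dt:
            raise ModelError("t_max must be at least one step")


@dataclass(frozen=True)
class SimulationResult:
    final_state: StateField
    converged: bool
    t_final: float
    trajectory: list[tuple[float, StateField]] | None = None
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# spatial operator
# ---------------------------------------------------------------------------

def transport_operators(
    template: CellTemplate, volume_scaled: bool = False
) -> tuple[csr_matrix, np.ndarray]:
    """Adjacency and degree of the miR171 transport operator.

    The default is the unweighted graph operator exactly as the model
    equation is written, with cell size folded into the single constant
    D_mir171.  ``volume_scaled=True`` enables the optional per-edge
    variant in which each edge weight is divided by the mean volume of
    the cell pair (normalised by the template's mean cell volume so the
    two modes share the scale of D); it remains off by default because
    the uniform rescaled constant is the reference reading.  Either
    operator is symmetric, so diffusion conserves total material.
    """
    if not volume_scaled:
        adj = template.adjacency()
    else:
        n = template.n_cells
        if not template.edges.size:
            adj = csr_matrix((n, n))
        else:
            i, j = template.edges[:, 0], template.edges[:, 1]
            v = template.volumes
            w = v.mean() / (0.5 * (v[i] + v[j]))
            rows = np.concatenate([i, j])
            cols = np.concatenate([j, i])
            adj = csr_matrix((np.concatenate([w, w]), (rows, cols)), shape=(n, n))
    deg = np.asarray(adj.sum(axis=1)).ravel()
    return adj, deg


def discrete_laplacian(values: np.ndarray, template: CellTemplate) -> np.ndarray:
    """Graph Laplacian contribution: out_i = sum_{n~i} (f_n - f_i).

    Boundary cells use only their existing neighbours (no-flux), so the
    output always sums to zero.  Accepts a single field of length
    n_cells or a batch of shape (..., n_cells).
    """
    values = np.asarray(values, dtype=float)
    if values.shape[-1] != template.n_cells:
        raise ModelError(
            f"field length {values.shape[-1]} != cell count {template.n_cells}"
        )
    adj = template.adjacency()
    deg = template.degrees()
    return values @ adj - values * deg


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------

def _rhs_stack(
    state: np.ndarray,           # (..., 5, n)
    ml1p: np.ndarray,            # (..., n)
    params: np.ndarray,          # (..., 12) broadcastable
    adj: csr_matrix,
    deg: np.ndarray,
) -> np.ndarray:
    p = {name: params[..., k, None] for k, name in enumerate(PARAM_NAMES)}
    mir, hamr, hamp, gfpr, gfpp = (state[..., k, :] for k in range(5))
    lap = mir @ adj - mir * deg
    d_mir = p["k_mirp"] * ml1p - p["k_mirn"] * mir + p["D_mir171"] * lap
    d_hamr = p["k_hrp"] - p["k_hrnm"] * hamr * mir - p["k_hrnh"] * hamr
    d_hamp = p["k_hpp"] * hamr - p["k_hpn"] * hamp
    d_gfpr = p["k_grp"] * ml1p - p["k_grn"] * gfpr
    d_gfpp = p["k_gpp"] * gfpr - p["k_gpn"] * gfpp
    return np.stack([d_mir, d_hamr, d_hamp, d_gfpr, d_gfpp], axis=-2)


def derivatives(
    state: StateField,
    ml1p: MLpField,
    params: ModelParameters,
    template: CellTemplate,
    volume_scaled_diffusion: bool = False,
) -> StateField:
    """Time derivative of every species in every cell (a.u./h)."""
    n = template.n_cells
    if state.n_cells != n or len(ml1p.values) != n:
        raise ModelError("state / input / template lengths disagree")
    adj, deg = transport_operators(template, volume_scaled_diffusion)
    d = _rhs_stack(state.stack(), ml1p.values, params.as_array(), adj, deg)
    return StateField.from_stack(d)


def single_cell_steady_state(ml1p_value: float, params: ModelParameters) -> SingleCellSteadyState:
    """Closed-form steady state of one isolated cell (no diffusion).

    miR171* = k_mirp M / k_mirn;
    HAMr*   = k_hrp / (k_hrnm miR171* + k_hrnh);
    HAMp*   = k_hpp HAMr* / k_hpn;
    GFPr*   = k_grp M / k_grn;  GFPp* = k_gpp GFPr* / k_gpn.
    """
    if ml1p_value < 0:
        raise ModelError("[ML1p] must be non-negative")
    mir = params.k_mirp * ml1p_value / params.k_mirn
    hamr = params.k_hrp / (params.k_hrnm * mir + params.k_hrnh)
    hamp = params.k_hpp * hamr / params.k_hpn
    gfpr = params.k_grp * ml1p_value / params.k_grn
    gfpp = params.k_gpp * gfpr / params.k_gpn
    return SingleCellSteadyState(mir, hamr, hamp, gfpr, gfpp)


def steady_state_linear(
    ml1p: MLpField, params: ModelParameters, template: CellTemplate
) -> StateField:
    """Steady state computed directly from the model's linear structure.

    The miR171 equation is linear, so its fixed point solves the sparse
    system (k_mirn I - D_mir171 Lap) m = k_mirp [ML1p]; every other
    species then follows elementwise.  This is an analytic cross-check
    for the time integrator, not the reference simulation path.
    """
    n = template.n_cells
    adj = template.adjacency()
    deg = template.degrees()
    lap = adj - csr_matrix((deg, (np.arange(n), np.arange(n))), shape=(n, n))
    A = params.k_mirn * sparse_eye(n, format="csr") - params.D_mir171 * lap
    mir = spsolve(A.tocsc(), params.k_mirp * ml1p.values)
    hamr = params.k_hrp / (params.k_hrnm * mir + params.k_hrnh)
    hamp = params.k_hpp * hamr / params.k_hpn
    gfpr = params.k_grp * ml1p.values / params.k_grn
    gfpp = params.k_gpp * gfpr / params.k_gpn
    return StateField(mir, hamr, hamp, gfpr, gfpp)


# ---------------------------------------------------------------------------
# forward-Euler integration
# ---------------------------------------------------------------------------

def stability_margin(
    ml1p: np.ndarray, params: np.ndarray, max_degree: float, dt: float
) -> np.ndarray:
    """dt times a bound on the fastest per-cell loss rate, per parameter set.

    The explicit Euler step is refused when this reaches 1.  The bound
    uses the a-priori miR171 ceiling k_mirp max[ML1p] / k_mirn (reached
    from a zero initial state only at steady state).
    """
    params = np.atleast_2d(params)
    ml1p = np.atleast_2d(ml1p)
    p = {name: params[:, k] for k, name in enumerate(PARAM_NAMES)}
    mir_max = p["k_mirp"] * ml1p.max(axis=1) / p["k_mirn"]
    loss = np.max(
        np.stack([
            p["k_mirn"] + p["D_mir171"] * max_degree,
            p["k_hrnm"] * mir_max + p["k_hrnh"],
            p["k_hpn"], p["k_grn"], p["k_gpn"],
        ]),
        axis=0,
    )
    return dt * loss


def _euler_batch(
    ml1p: np.ndarray,     # (B, n)
    params: np.ndarray,   # (B, 12)
    template: CellTemplate,
    config: SimulationConfig,
    record: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list]:
    """Integrate a batch of independent runs sharing one template.

    Returns (final states (B,5,n), converged (B,), diverged (B,),
    t_final (B,), trajectory).  Rows that reach the steady tolerance are
    frozen and removed from the active batch; divergent rows are frozen
    and flagged instead of raising, so sweeps never abort.
    """
    B, n = ml1p.shape
    adj, deg = transport_operators(template, config.volume_scaled_diffusion)
    dt = config.dt
    n_steps = int(round(config.t_max / dt))

    margin = stability_margin(ml1p, params, float(deg.max(initial=0.0)), dt)
    unstable = margin >= 1.0
    if np.any(unstable) and not config.allow_unstable:
        raise StabilityError(
            f"dt={dt} violates the explicit-Euler stability bound for "
            f"{int(unstable.sum())}/{B} parameter set(s) (max margin "
            f"{margin.max():.3g} >= 1); reduce dt or set allow_unstable"
        )

    state = np.zeros((B, 5, n))
    final = np.zeros_like(state)
    converged = np.zeros(B, dtype=bool)
    diverged = np.zeros(B, dtype=bool)
    t_final = np.full(B, n_steps * dt)
    active = np.arange(B)
    trajectory: list[tuple[float, np.ndarray]] = []

    def _columns(p):
        return {name: p[:, k, None] for k, name in enumerate(PARAM_NAMES)}

    p = _columns(params)
    for step in range(1, n_steps + 1):
        mir, hamr, hamp, gfpr, gfpp = (state[:, k, :] for k in range(5))
        lap = mir @ adj
        lap -= mir * deg
        d0 = p["k_mirp"] * ml1p - p["k_mirn"] * mir + p["D_mir171"] * lap
        d1 = p["k_hrp"] - (p["k_hrnm"] * mir + p["k_hrnh"]) * hamr
        d2 = p["k_hpp"] * hamr - p["k_hpn"] * hamp
        d3 = p["k_grp"] * ml1p - p["k_grn"] * gfpr
        d4 = p["k_gpp"] * gfpr - p["k_gpn"] * gfpp
        mir += dt * d0
        hamr += dt * d1
        hamp += dt * d2
        gfpr += dt * d3
        gfpp += dt * d4
        t = step * dt

        if record and config.record_every and step % config.record_every == 0:
            trajectory.append((t, state[0].copy()))

        max_d = np.max(
            np.stack([
                np.max(np.abs(d0), axis=1), np.max(np.abs(d1), axis=1),
                np.max(np.abs(d2), axis=1), np.max(np.abs(d3), axis=1),
                np.max(np.abs(d4), axis=1),
            ]),
            axis=0,
        )
        bad = ~np.isfinite(max_d) | (np.max(state, axis=(1, 2)) > config.ceiling)
        done = (max_d < config.steady_tol) | bad
        if np.any(done):
            idx = np.nonzero(done)[0]
            final[active[idx]] = state[idx]
            converged[active[idx]] = ~bad[idx]
            diverged[active[idx]] = bad[idx]
            t_final[active[idx]] = t
            keep = ~done
            if not np.any(keep):
                return final, converged, diverged, t_final, trajectory
            state = np.ascontiguousarray(state[keep])
            ml1p = ml1p[keep]
            params = params[keep]
            p = _columns(params)
            active = active[keep]
    final[active] = state
    return final, converged, diverged, t_final, trajectory


def integrate_euler(
    ml1p: MLpField,
    params: ModelParameters,
    template: CellTemplate,
    config: SimulationConfig | None = None,
) -> SimulationResult:
    """Integrate the cascade from the all-zero state to steady state.

    Explicit forward Euler with the fixed step ``config.dt``; stops when
    every per-cell, per-species derivative magnitude drops below
    ``config.steady_tol`` or at ``config.t_max``.  Raises
    :class:`StabilityError` for a step size that violates the stability
    guard and :class:`DivergenceError` if any concentration blows up.
    """
    config = config or SimulationConfig()
    n = template.n_cells
    if len(ml1p.values) != n:
        raise ModelError("input field length does not match the template")
    final, converged, diverged, t_final, traj = _euler_batch(
        ml1p.values[None, :],
        params.as_array()[None, :],
        template,
        config,
        record=config.record_every > 0,
    )
    if diverged[0]:
        raise DivergenceError(
            f"simulation diverged before t={t_final[0]:.2f} h (ceiling {config.ceiling:g})"
        )
    if not converged[0]:
        warnings.warn(
            f"steady state not reached by t_max={config.t_max} h", stacklevel=2
        )
    trajectory = (
        [(t, StateField.from_stack(s)) for t, s in traj] if config.record_every else None
    )
    return SimulationResult(
        final_state=StateField.from_stack(final[0]),
        converged=bool(converged[0]),
        t_final=float(t_final[0]),
        trajectory=trajectory,
        provenance={
            "params": params.to_dict(),
            "config": {
                "dt": config.dt, "t_max": config.t_max,
                "steady_tol": config.steady_tol,
            },
            "template_checksum": template.checksum(),
            "ml1p_label": ml1p.label,
        },
    )


def integrate_euler_many(
    fields: list[MLpField],
    params: ModelParameters,
    template: CellTemplate,
    config: SimulationConfig | None = None,
) -> list[SimulationResult]:
    """Integrate several input fields with one parameter set, batched.

    Equivalent to calling :func:`integrate_euler` per field (each row of
    the batch performs the identical arithmetic), but advances all runs
    in lock-step for throughput.  Divergent runs raise, as in the
    single-run path.
    """
    config = config or SimulationConfig()
    n = template.n_cells
    for f in fields:
        if len(f.values) != n:
            raise ModelError("input field length does not match the template")
    ml1p = np.array([f.values for f in fields])
    pmat = np.repeat(params.as_array()[None, :], len(fields), axis=0)
    finals, converged, diverged, t_final, _ = _euler_batch(ml1p, pmat, template, config)
    if np.any(diverged):
        labels = [fields[i].label for i in np.nonzero(diverged)[0]]
        raise DivergenceError(f"simulation diverged for input(s): {labels}")
    checksum = template.checksum()
    results = []
    for k, f in enumerate(fields):
        if not converged[k]:
            warnings.warn(
                f"steady state not reached by t_max={config.t_max} h for {f.label}",
                stacklevel=2,
            )
        results.append(
            SimulationResult(
                final_state=StateField.from_stack(finals[k]),
                converged=bool(converged[k]),
                t_final=float(t_final[k]),
                provenance={
                    "params": params.to_dict(),
                    "config": {"dt": config.dt, "t_max": config.t_max,
                               "steady_tol": config.steady_tol},
                    "template_checksum": checksum,
                    "ml1p_label": f.label,
                },
            )
        )
    return results


# ---------------------------------------------------------------------------
# summaries and I/O
# ---------------------------------------------------------------------------

def layer_means(
    state: StateField, template: CellTemplate, species: str
) -> dict[str, float]:
    """Arithmetic mean of one species over L1, L2 and CORPUS."""
    if species not in SPECIES:
        raise ModelError(f"unknown species {species!r}")
    values = getattr(state, species)
    out = {}
    for layer in LAYERS:
        mask = template.layer_mask(layer)
        if not np.any(mask):
            raise ModelError(f"layer {layer} is empty")
        out[layer] = float(values[mask].mean())
    return out


def total_ham_mrna(state: StateField) -> float:
    """Template-wide sum of steady-state HAM mRNA, the screening output m."""
    return float(state.ham_mrna.sum())


def write_result_csv(result: SimulationResult, template: CellTemplate, path: str | Path) -> None:
    df = pd.DataFrame({"id": np.arange(template.n_cells), "layer": template.layers})
    for s in SPECIES:
        df[s] = getattr(result.final_state, s)
    df.to_csv(path, index=False)


def write_params_csv(sets: list[ModelParameters], path: str | Path) -> None:
    rows = [{"id": i, **p.to_dict()} for i, p in enumerate(sets)]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_params_csv(path: str | Path) -> list[ModelParameters]:
    df = pd.read_csv(path)
    return [
        ModelParameters(**{k: float(row[k]) for k in PARAM_NAMES})
        for _, row in df.iterrows()
    ]
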