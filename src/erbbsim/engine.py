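"""Simulation driver: state initialization, stepping and replicate runs.

The engine advances 31 ErbB2 and 31 ErbB3 receptors (counts configurable)
through Brownian diffusion in a periodic box, transient confinement in
species-tagged domains (free entry, escape-probability-gated exit),
conformational gating of unliganded ErbB3, binding-radius dimerization,
exponential dissociation to the unbinding radius, and the asymmetric
activator/receiver phosphorylation scheme.

Each timestep applies, in a fixed order: conformation update, diffusion
proposals with boundary resolution (domain edges first, then the periodic
outer boundary), dissociation attempts, dimerization attempts, and
phosphorylation/dephosphorylation.  Observations are recorded on a fixed
grid (default every 0.05 s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel
from .binding import compute_binding_radius
from .landscape import Landscape
from .parameters import ParameterSet, rate_to_step_probability

#: DataFrame column names, aligned with the kernel's observation channels
COLUMNS = (
    "time",
    "erbb2_monomers",
    "erbb3_monomers",
    "heterodimers",
    "erbb3_homodimers",
    "erbb2_homodimers",
    "erbb2_phos",
    "erbb3_phos",
    "erbb3_phos_sites",
    "erbb2_in_domain",
    "erbb3_in_domain",
    "erbb3_open_monomers",
)

#: dimer composition kind index: species codes sum (0: 2/2, 1: 2/3, 2: 3/3)
KIND_NAMES = {0: "ErbB2/ErbB2", 1: "ErbB2/ErbB3", 2: "ErbB3/ErbB3"}


class SimulationInvariantError(RuntimeError):
    """Raised when a conservation or consistency invariant is violated."""


@dataclass
class SimState:
    """Mutable per-particle state of one simulation."""

    landscape: Landscape
    species: np.ndarray
    pos: np.ndarray
    liganded: np.ndarray
    open_: np.ndarray
    phos: np.ndarray
    partner: np.ndarray
    role: np.ndarray
    time: float = 0.0

    @property
    def n(self) -> int:
        return self.species.size

    def n_species(self, code: int) -> int:
        return int((self.species == code).sum())

    def check_invariants(self) -> None:
        """Partner symmetry, role complementarity, positions in box."""
        for i in range(self.n):
            j = self.partner[i]
            if j >= 0:
                if self.partner[j] != i:
                    raise SimulationInvariantError(
                        f"asymmetric partner link {i} -> {j} -> {self.partner[j]}"
                    )
                if self.role[i] == self.role[j] or self.role[i] == 0:
                    raise SimulationInvariantError(
                        f"dimer ({i}, {j}) roles must be one activator, one receiver"
                    )
            elif self.role[i] != 0:
                raise SimulationInvariantError(f"monomer {i} carries a dimer role")
        if np.any(self.pos < 0) or np.any(self.pos[:, 0] >= self.landscape.width) or np.any(
            self.pos[:, 1] >= self.landscape.height
        ):
            raise SimulationInvariantError("particle position outside the box")


def initialize(
    landscape: Landscape,
    *,
    n_erbb2: int = 31,
    n_erbb3: int = 31,
    ligand_fraction: float = 1.0,
    seed: int = 0,
) -> SimState:
    """Place receptors uniformly at random over their own species' domains
    plus the free area (never inside only the other species' domains),
    all monomeric and unphosphorylated.

    A uniformly random subset of ``round(ligand_fraction * n_erbb3)`` ErbB3
    receptors is ligand-bound; ligand occupancy is static for the run.
    """
    if n_erbb2 <= 0 or n_erbb3 <= 0:
        raise ValueError("receptor counts must be positive")
    if not 0.0 <= ligand_fraction <= 1.0:
        raise ValueError("ligand_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = n_erbb2 + n_erbb3
    species = np.concatenate(
        [np.zeros(n_erbb2, dtype=np.int64), np.ones(n_erbb3, dtype=np.int64)]
    )
    pos = np.zeros((n, 2))
    rects, codes = landscape.rect_arrays()
    for i in range(n):
        s = species[i]
        for _ in range(100_000):
            x = rng.uniform(0.0, landscape.width)
            y = rng.uniform(0.0, landscape.height)
            inside_other = False
            inside_own = False
            for mi in range(rects.shape[0]):
                r = rects[mi]
                if r[0] <= x < r[2] and r[1] <= y < r[3]:
                    if codes[mi] == s:
                        inside_own = True
                    else:
                        inside_other = True
            if inside_own or not inside_other:
                pos[i] = (x, y)
                break
        else:  # pragma: no cover
            raise RuntimeError("could not place a receptor; landscape overfull")
    liganded = np.zeros(n, dtype=bool)
    n_lig = int(round(ligand_fraction * n_erbb3))
    lig_idx = rng.choice(np.arange(n_erbb2, n), size=n_lig, replace=False)
    liganded[lig_idx] = True
    open_ = (species == 0) | liganded
    return SimState(
        landscape=landscape,
        species=species,
        pos=pos,
        liganded=liganded,
        open_=open_,
        phos=np.zeros((n, 2), dtype=bool),
        partner=np.full(n, -1, dtype=np.int64),
        role=np.zeros(n, dtype=np.int64),
    )


def binding_radii(params: ParameterSet, dt: float) -> np.ndarray:
    """Binding radii per composition kind [2/2, 2/3, 3/3], calibrated for
    ``dt`` (cached across calls)."""
    D2 = params.D_monomer["ErbB2"]
    D3 = params.D_monomer["ErbB3"]
    mutual = (2.0 * D2, D2 + D3, 2.0 * D3)
    return np.array(
        [compute_binding_radius(params.k_on_2d, Dm, dt) for Dm in mutual]
    )


def _kernel_tables(params: ParameterSet, dt: float, escape_scaling: float):
    D_mono = np.array([params.D_monomer["ErbB2"], params.D_monomer["ErbB3"]])
    D_dim = np.array(
        [
            params.D_dimer["ErbB2/ErbB2"],
            params.D_dimer["ErbB2/ErbB3"],
            params.D_dimer["ErbB3/ErbB3"],
        ]
    )
    p_off = np.zeros((3, 3))
    for k, kind in KIND_NAMES.items():
        for nl, k_off in enumerate(params.k_off[kind]):
            p_off[k, nl] = rate_to_step_probability(k_off, dt)
    p_phos = np.array(
        [rate_to_step_probability(params.k_phos[sp], dt) for sp in ("ErbB2", "ErbB3")]
    )
    p_basal = np.array(
        [
            rate_to_step_probability(params.k_phos_basal[sp], dt)
            for sp in ("ErbB2", "ErbB3")
        ]
    )
    p_deph = np.zeros((2, 2))
    p_deph[0, 0] = rate_to_step_probability(params.k_dephos["ErbB2"]["PY"], dt)
    p_deph[1, 0] = rate_to_step_probability(params.k_dephos["ErbB3"]["PY1197"], dt)
    p_deph[1, 1] = rate_to_step_probability(params.k_dephos["ErbB3"]["PY1289"], dt)
    # escape, indexed [mono ErbB2, mono ErbB3, 2/2 dimer, 2/3 dimer, 3/3 dimer]
    esc = np.array(
        [
            params.lookup_escape("ErbB2 monomer", escape_scaling),
            params.lookup_escape("ErbB3 monomer", escape_scaling),
            params.lookup_escape("ErbB2/ErbB2 dimer", escape_scaling),
            params.lookup_escape("ErbB2/ErbB3 dimer", escape_scaling),
            params.lookup_escape("ErbB3/ErbB3 dimer", escape_scaling),
        ]
    )
    return D_mono, D_dim, p_off, p_phos, p_basal, p_deph, esc


def advance(
    state: SimState,
    params: ParameterSet,
    *,
    duration: float,
    dt: float | None = None,
    obs_interval: float = 0.05,
    escape_scaling: float = 1.0,
    seed: int = 0,
    record_states: bool = False,
    r_b: np.ndarray | None = None,
) -> pd.DataFrame:
    """Advance ``state`` in place for ``duration`` seconds and return the
    observation time series (row 0 is the state on entry).

    ``r_b`` overrides the calibrated binding radii (testing hook).  The
    species-conservation identity is checked on every observation row.
    """
    dt = params.dt if dt is None else dt
    if dt <= 0 or duration < 0:
        raise ValueError("need dt > 0 and duration >= 0")
    obs_every = max(1, int(round(obs_interval / dt)))
    n_steps = int(round(duration / dt))
    if r_b is None:
        r_b = binding_radii(params, dt)
    D_mono, D_dim, p_off, p_phos, p_basal, p_deph, esc = _kernel_tables(
        params, dt, escape_scaling
    )
    rects, codes = state.landscape.rect_arrays()
    n_obs = n_steps // obs_every + 1
    out = np.zeros((n_obs, _kernel.NCH))
    states = (
        np.zeros((n_obs, state.n), dtype=np.int8)
        if record_states
        else np.zeros((1, 1), dtype=np.int8)
    )
    rows = _kernel.run(
        seed,
        n_steps,
        obs_every,
        state.time,
        dt,
        state.pos,
        state.species,
        state.liganded,
        state.open_,
        state.phos,
        state.partner,
        state.role,
        rects,
        codes,
        state.landscape.width,
        state.landscape.height,
        D_mono,
        D_dim,
        r_b,
        p_off,
        p_phos,
        p_basal,
        p_deph,
        params.p_open,
        esc,
        params.erbb2_homodimer_on_multiplier,
        params.unbind_factor,
        out,
        states,
        record_states,
    )
    state.time += n_steps * dt
    df = pd.DataFrame(out[:rows], columns=COLUMNS)
    _check_conservation(df, state.n_species(0), state.n_species(1))
    state.check_invariants()
    if record_states:
        df.attrs["receptor_states"] = states[:rows]
    return df


def _check_conservation(df: pd.DataFrame, n2: int, n3: int) -> None:
    tot2 = df["erbb2_monomers"] + df["heterodimers"] + 2 * df["erbb2_homodimers"]
    tot3 = df["erbb3_monomers"] + df["heterodimers"] + 2 * df["erbb3_homodimers"]
    if not (np.all(tot2 == n2) and np.all(tot3 == n3)):
        raise SimulationInvariantError(
            "species conservation violated: monomers + dimer members must equal "
            f"{n2} ErbB2 and {n3} ErbB3 at every observation"
        )


def simulate(
    landscape: Landscape,
    params: ParameterSet | None = None,
    *,
    ligand_fraction: float = 1.0,
    escape_scaling: float = 1.0,
    duration: float = 240.0,
    dt: float | None = None,
    obs_interval: float = 0.05,
    seed: int = 0,
    n_erbb2: int = 31,
    n_erbb3: int = 31,
    record_states: bool = False,
) -> pd.DataFrame:
    """Run one full simulation from a fresh random initial state."""
    params = ParameterSet() if params is None else params
    state = initialize(
        landscape,
        n_erbb2=n_erbb2,
        n_erbb3=n_erbb3,
        ligand_fraction=ligand_fraction,
        seed=seed,
    )
    return advance(
        state,
        params,
        duration=duration,
        dt=dt,
        obs_interval=obs_interval,
        escape_scaling=escape_scaling,
        seed=seed,
        record_states=record_states,
    )


def simulate_replicates(
    landscape: Landscape,
    params: ParameterSet | None = None,
    *,
    n_runs: int = 4,
    base_seed: int = 0,
    **kwargs,
) -> list[pd.DataFrame]:
    """``n_runs`` independent replicates; replicate ``r`` uses seed
    ``base_seed + r``."""
    return [
        simulate(landscape, params, seed=base_seed + r, **kwargs)
        for r in range(n_runs)
    ]
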