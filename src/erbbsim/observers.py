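"""Time-series bookkeeping, steady-state summaries and experiment grids.

A simulation emits one observation row per 0.05 s with monomer, dimer and
phosphorylation counts (see :data:`erbbsim.engine.COLUMNS`).  Steady-state
quantities are time-averages over a terminal window of each run, reported
as mean +- sample SD across replicate runs.  "Total phosphorylation" of a
species counts receptors carrying at least one phosphate; a per-site
tally (``erbb3_phos_sites``) is also emitted so a site-level reading is
recoverable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .engine import COLUMNS, simulate_replicates
from .landscape import (
    Landscape,
    build_empty_landscape,
    build_fixture_landscape,
)
from .parameters import ParameterSet

#: quantities summarised at steady state
QUANTITIES = (
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
)


def snapshot_counts(state) -> dict:
    """Observation-row bookkeeping for a :class:`~erbbsim.engine.SimState`
    (reference implementation of the per-row counts, used in tests)."""
    sp = state.species
    partner = state.partner
    phos = state.phos
    is_dimer = partner >= 0
    lead = is_dimer & (partner > np.arange(state.n))
    kind = sp + sp[np.where(partner >= 0, partner, 0)]
    row = {
        "erbb2_monomers": int(((sp == 0) & ~is_dimer).sum()),
        "erbb3_monomers": int(((sp == 1) & ~is_dimer).sum()),
        "heterodimers": int((lead & (kind == 1)).sum()),
        "erbb3_homodimers": int((lead & (kind == 2)).sum()),
        "erbb2_homodimers": int((lead & (kind == 0)).sum()),
        "erbb2_phos": int(((sp == 0) & phos[:, 0]).sum()),
        "erbb3_phos": int(((sp == 1) & (phos[:, 0] | phos[:, 1])).sum()),
        "erbb3_phos_sites": int(phos[sp == 1].sum()),
    }
    in2 = in3 = 0
    for i in range(state.n):
        for d in state.landscape.domains:
            if d.species == ("ErbB2" if sp[i] == 0 else "ErbB3") and d.contains(
                state.pos[i, 0], state.pos[i, 1]
            ):
                if sp[i] == 0:
                    in2 += 1
                else:
                    in3 += 1
                break
    row["erbb2_in_domain"] = in2
    row["erbb3_in_domain"] = in3
    return row


def percent_change(reference: float, comparison: float) -> float:
    """Signed percent change of ``comparison`` relative to ``reference``:
    ``100 * (comparison - reference) / reference``."""
    if reference == 0:
        raise ZeroDivisionError(
            "percent change undefined for a zero reference quantity"
        )
    return 100.0 * (comparison - reference) / reference


def window_average(series: pd.DataFrame, window: float) -> pd.Series:
    """Time-average of each quantity over the final ``window`` seconds."""
    t_end = float(series["time"].iloc[-1])
    if window > t_end - float(series["time"].iloc[0]):
        raise ValueError(
            f"averaging window {window} s exceeds the series span"
        )
    sel = series["time"] >= t_end - window
    return series.loc[sel, list(QUANTITIES)].mean()


def steady_state_summary(
    series_list: list[pd.DataFrame], window: float = 40.0
) -> pd.DataFrame:
    """Per-quantity mean and sample SD across runs of the terminal
    time-averages.

    Returns a DataFrame indexed by quantity with columns ``mean``, ``sd``
    and ``n_runs``; with a single run the SD is NaN.
    """
    if not series_list:
        raise ValueError("need at least one run")
    per_run = pd.DataFrame([window_average(s, window) for s in series_list])
    out = pd.DataFrame(
        {
            "mean": per_run.mean(),
            "sd": per_run.std(ddof=1),
            "n_runs": len(series_list),
        }
    )
    out.index.name = "quantity"
    return out


def landscape_for(spec, seed: int) -> Landscape:
    """Resolve a landscape spec: ``"none"`` (empty), a float overlap
    fraction, or a path to a landscape table."""
    if isinstance(spec, str) and spec != "none":
        return Landscape.from_tsv(spec)
    if spec == "none" or spec is None:
        return build_empty_landscape()
    return build_fixture_landscape(float(spec), seed)


def run_experiment_grid(
    *,
    overlaps=("none",),
    ligand_fractions=(1.0,),
    escape_scalings=(1.0,),
    params: ParameterSet | None = None,
    duration: float = 240.0,
    dt: float | None = None,
    n_runs: int = 4,
    base_seed: int = 0,
    window: float = 40.0,
    landscape_seed: int | None = None,
) -> pd.DataFrame:
    """Replicated simulations over a (overlap x ligand x escape-scaling)
    grid; returns a tidy table with one row per cell and quantity.

    Each overlap level uses one fixture landscape (seeded from
    ``landscape_seed``, default ``base_seed``), shared across the other
    axes so escape and ligand comparisons see identical geometry.
    """
    params = ParameterSet() if params is None else params
    if landscape_seed is None:
        landscape_seed = base_seed
    rows = []
    for overlap in overlaps:
        ls = landscape_for(overlap, landscape_seed)
        for lig in ligand_fractions:
            for scaling in escape_scalings:
                runs = simulate_replicates(
                    ls,
                    params,
                    n_runs=n_runs,
                    base_seed=base_seed,
                    ligand_fraction=lig,
                    escape_scaling=scaling,
                    duration=duration,
                    dt=dt,
                )
                summ = steady_state_summary(runs, window=window)
                for q in QUANTITIES:
                    rows.append(
                        {
                            "overlap": overlap,
                            "ligand_fraction": lig,
                            "escape_scaling": scaling,
                            "quantity": q,
                            "mean": summ.loc[q, "mean"],
                            "sd": summ.loc[q, "sd"],
                            "n_runs": n_runs,
                            "window_s": window,
                        }
                    )
    return pd.DataFrame(rows)


def grid_value(table: pd.DataFrame, overlap, scaling, quantity,
               ligand_fraction=None) -> tuple[float, float]:
    """(mean, sd) of one cell/quantity from a tidy grid table."""
    sel = (
        (table["overlap"] == overlap)
        & (table["escape_scaling"] == scaling)
        & (table["quantity"] == quantity)
    )
    if ligand_fraction is not None:
        sel &= table["ligand_fraction"] == ligand_fraction
    hit = table[sel]
    if len(hit) != 1:
        raise KeyError(
            f"grid lookup ({overlap}, {scaling}, {quantity}) matched {len(hit)} rows"
        )
    return float(hit["mean"].iloc[0]), float(hit["sd"].iloc[0])
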