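"""Parameter-sweep orchestration.

A campaign samples configurations of the seven active inputs, runs a few
replicate simulations of each (4-6 at full scale), reduces every curve to
its logistic summaries and assembles one table row per configuration with
replicate-averaged ⟨A⟩, ⟨μ⟩, ⟨τ⟩.  The full-scale protocol is 3,358
configurations × 4-6 replicates (≈18,000 runs); a desk-scale campaign of
120 configurations × 4 replicates on a coarser 61×61 lattice (10 μm patch
side) is the documented proxy used for campaign-level statistics.

Replicate seeds are a pure function of (master_seed, config_id,
replicate_index), so any single row can be reproduced in isolation and the
assembled dataset is independent of worker count and completion order.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import engine
from .config import ParameterSet, sample_configurations
from .growth import average_outputs, fit_growth

__all__ = [
    "replicate_seed",
    "replicate_count",
    "run_configuration",
    "run_campaign",
    "split_by_steptime",
    "train_test_split",
    "ACTIVE_INPUT_COLUMNS",
    "DESK_SCALE",
]

logger = logging.getLogger(__name__)

ACTIVE_INPUT_COLUMNS = [
    "pmax",
    "microorganism",
    "depth",
    "umax_pa",
    "diffusion_coefficient",
    "glucose",
    "steptime",
]

#: desk-scale campaign used for campaign-level statistics
DESK_SCALE = dict(n_configs=120, reps_min=4, reps_max=4, patch_side_um=10.0, t_max_h=18.0)


def replicate_seed(master_seed: int, config_id: int, replicate_index: int) -> int:
    """Deterministic per-replicate seed (counter-based, independent streams)."""
    ss = np.random.SeedSequence((master_seed, config_id, replicate_index))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def replicate_count(master_seed: int, config_id: int, reps_min: int, reps_max: int) -> int:
    """Replicate count for one configuration, drawn uniformly in [min, max]."""
    ss = np.random.SeedSequence((master_seed, config_id, 999_983))
    rng = np.random.default_rng(ss)
    return int(rng.integers(reps_min, reps_max + 1))


def run_configuration(
    p: ParameterSet,
    config_id: int,
    master_seed: int,
    n_reps: int,
    t_max_h: float = 18.0,
    patch_side_um: float = engine.DEFAULT_PATCH_SIDE_UM,
    fit_spaces: tuple[str, ...] = ("counts", "log_ratio"),
    keep_curves: bool = False,
) -> dict | None:
    """Run all replicates of one configuration and average the fits.

    Returns one dataset row, or ``None`` when no replicate yields a
    converged fit in the primary (first) fit space.
    """
    curves = []
    for rep in range(n_reps):
        seed = replicate_seed(master_seed, config_id, rep)
        curve = engine.run(p, seed, t_max_h=t_max_h, patch_side_um=patch_side_um)
        curve.parameter_set_id = config_id
        curves.append(curve)

    row: dict = {"config_id": config_id, **p.active_values, "n_replicates": n_reps}
    primary = fit_spaces[0]
    for space in fit_spaces:
        fits = [fit_growth(c, fit_space=space) for c in curves]
        n_conv = sum(f.converged for f in fits)
        suffix = "" if space == primary else f"_{space}"
        if n_conv == 0:
            if space == primary:
                logger.warning("config %d: no converged %s fits; row dropped", config_id, space)
                return None
            row.update({f"A{suffix}": np.nan, f"mu{suffix}": np.nan, f"tau{suffix}": np.nan,
                        f"n_converged{suffix}": 0})
            continue
        avg = average_outputs(fits)
        row.update(
            {
                f"A{suffix}": avg.A_mean,
                f"mu{suffix}": avg.mu_mean,
                f"tau{suffix}": avg.tau_mean,
                f"A_sd{suffix}": avg.A_sd,
                f"mu_sd{suffix}": avg.mu_sd,
                f"tau_sd{suffix}": avg.tau_sd,
                f"n_converged{suffix}": avg.n_converged,
            }
        )
    if keep_curves:
        row["curves"] = curves
    return row


def run_campaign(
    n_configs: int,
    reps_min: int = 4,
    reps_max: int = 6,
    master_seed: int = 0,
    t_max_h: float = 18.0,
    patch_side_um: float = engine.DEFAULT_PATCH_SIDE_UM,
    workers: int = 1,
    fit_spaces: tuple[str, ...] = ("counts", "log_ratio"),
) -> pd.DataFrame:
    """Sample, simulate, fit and assemble the campaign dataset.

    One row per configuration that produced at least one converged fit:
    the seven active inputs plus replicate-averaged A, mu, tau (and SDs) in
    each requested fit space (the first is the primary, unsuffixed one).
    The result is byte-identical for a fixed ``master_seed`` regardless of
    ``workers``.
    """
    if not (1 <= reps_min <= reps_max):
        raise ValueError("need 1 <= reps_min <= reps_max")
    configs = sample_configurations(n_configs, master_seed)
    jobs = [
        (p, cid, replicate_count(master_seed, cid, reps_min, reps_max))
        for cid, p in enumerate(configs)
    ]
    if workers == 1:
        rows = [
            run_configuration(p, cid, master_seed, nr, t_max_h, patch_side_um, fit_spaces)
            for p, cid, nr in jobs
        ]
    else:
        rows = Parallel(n_jobs=workers)(
            delayed(run_configuration)(
                p, cid, master_seed, nr, t_max_h, patch_side_um, fit_spaces
            )
            for p, cid, nr in jobs
        )
    rows = [r for r in rows if r is not None]
    if not rows:
        logger.warning("campaign produced no converged configurations")
        return pd.DataFrame(columns=["config_id", *ACTIVE_INPUT_COLUMNS,
                                     "n_replicates", "A", "mu", "tau"])
    df = pd.DataFrame(rows)
    return df.sort_values("config_id").reset_index(drop=True)


def split_by_steptime(dataset: pd.DataFrame) -> dict[float, pd.DataFrame]:
    """Partition the dataset by its exact steptime value (four sub-datasets)."""
    if dataset.empty:
        raise ValueError("dataset is empty")
    from .config import CAMPAIGN_STEPTIMES

    known = set(np.round(CAMPAIGN_STEPTIMES, 10))
    values = set(np.round(dataset["steptime"].unique(), 10))
    unknown = values - known
    if unknown:
        raise ValueError(f"unknown steptime values {sorted(unknown)}")
    out = {}
    for st in CAMPAIGN_STEPTIMES:
        sub = dataset[np.isclose(dataset["steptime"], st)]
        if sub.empty:
            logger.warning("steptime %.1f: empty subset", st)
        out[st] = sub.reset_index(drop=True)
    return out


def train_test_split(
    dataset: pd.DataFrame, ratio: float = 0.7, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded uniform split without replacement; |train| = round(ratio·n)."""
    if not (0.0 < ratio < 1.0):
        raise ValueError("ratio must be in (0, 1)")
    n = len(dataset)
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    k = int(round(ratio * n))
    train = dataset.iloc[np.sort(perm[:k])].reset_index(drop=True)
    test = dataset.iloc[np.sort(perm[k:])].reset_index(drop=True)
    return train, test
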