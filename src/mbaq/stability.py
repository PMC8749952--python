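"""Bootstrap analysis of median stability vs number of standard peptides.

How many equimolar peptides does the standard need before its median XIC
area is a stable calibrant?  For each subset size k, k peptide areas are
drawn without replacement and their median recorded, over ``n_iter``
iterations; the spread of those medians (their CV, %) as a function of k
shows where the median stabilizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .quantify import cv_percent

logger = logging.getLogger("mbaq")

#: Plateau rule: relative spread change over the next two larger k values.
PLATEAU_REL_CHANGE = 0.10


@dataclass
class BootstrapRun:
    k: int
    n_iter: int
    seed: int
    medians: list[float]

    @property
    def spread_percent(self) -> float:
        """CV (%) of the iteration medians; 0 when all medians coincide."""
        arr = np.asarray(self.medians)
        if np.allclose(arr, arr[0]):
            return 0.0
        return cv_percent(self.medians)

    @property
    def median_of_medians(self) -> float:
        return float(np.median(self.medians))


def bootstrap_median(
    areas: list[float], k: int, n_iter: int = 100, seed: int = 0, replace: bool = False
) -> BootstrapRun:
    """Sample k areas (without replacement by default) n_iter times."""
    arr = np.asarray(areas, dtype=float)
    if arr.size == 0 or np.any(arr <= 0):
        raise ValidationError("areas must be positive")
    if not 1 <= k <= arr.size:
        raise ValidationError(f"k={k} outside [1, {arr.size}]")
    rng = np.random.default_rng(seed)
    medians = [
        float(np.median(rng.choice(arr, size=k, replace=replace))) for _ in range(n_iter)
    ]
    return BootstrapRun(k=k, n_iter=n_iter, seed=seed, medians=medians)


def median_spread_profile(
    areas: list[float],
    k_values=range(3, 121),
    n_iter: int = 100,
    seed: int = 0,
    replace: bool = False,
) -> pd.DataFrame:
    """Spread profile over k: columns (k, spread_percent, median_of_medians)."""
    k_values = list(k_values)
    if not k_values:
        raise ValidationError("empty k_values")
    if max(k_values) > len(areas):
        raise ValidationError(f"k={max(k_values)} exceeds the pool size {len(areas)}")
    rows = []
    for k in k_values:
        # independent, reproducible stream per k
        child_seed = int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % 2**31)
        run = bootstrap_median(areas, k, n_iter=n_iter, seed=child_seed, replace=replace)
        rows.append((k, run.spread_percent, run.median_of_medians))
    return pd.DataFrame(rows, columns=["k", "spread_percent", "median_of_medians"])


def recommend_min_peptides(profile: pd.DataFrame, spread_threshold_percent: float) -> int:
    """Smallest k whose spread is below threshold and already on the plateau.

    Plateau: the spread changes by less than 10% (relative) over the next
    two larger k values in the profile.  When no k satisfies both rules the
    largest profiled k is returned with a warning.
    """
    if profile is None or len(profile) == 0:
        raise ValidationError("empty spread profile")
    prof = profile.sort_values("k").reset_index(drop=True)
    spreads = prof["spread_percent"].to_numpy()
    ks = prof["k"].to_numpy()
    for i, (k, s) in enumerate(zip(ks, spreads)):
        if s > spread_threshold_percent:
            continue
        nxt = spreads[i + 1 : i + 3]
        if s == 0:
            on_plateau = bool(np.all(nxt == 0))
        else:
            on_plateau = bool(np.all(np.abs(nxt - s) / s < PLATEAU_REL_CHANGE))
        if on_plateau:
            return int(k)
    logger.warning(
        "no k reached spread <= %.3g%% with a plateau; returning the largest profiled k",
        spread_threshold_percent,
    )
    return int(ks[-1])


def write_profile(profile: pd.DataFrame, path) -> None:
    profile.to_csv(path, sep="\t", index=False)


def plot_profile(profile: pd.DataFrame, path) -> None:
    """Optional spread-vs-k plot (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(profile["k"], profile["spread_percent"], marker="d", lw=1)
    ax.set_xlabel("peptides per draw (k)")
    ax.set_ylabel("spread of bootstrap medians (CV, %)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
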