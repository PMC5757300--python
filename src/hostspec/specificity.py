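"""Functional-phylogenetic host specificity.

The pairwise host distance blends phylogeny and ecological niche,

    FPDist = (a * PDist**p + (1 - a) * FDist**p) ** (1/p),

with weight ``a`` in [0, 1] (1 = pure phylogeny, 0 = pure niche) and
exponent ``p`` (2 by default, i.e. squared-Euclidean blending). A
parasite's specificity index STD* is the mean pairwise FPDist among its
hosts; low values mean the parasite is confined to similar hosts.

The permutation null redraws, for each of many iterations, a weight
``a ~ U(0,1)``, one dendrogram from the niche ensemble, and an equal-size
uniform host set from the sampled pool; the observed-minus-expected STD*
differential is negative when the parasite's hosts are more similar than
chance (clustered) and positive when they are overdispersed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .distances import Dendrogram
from .io import AnalysisConfig, DistanceMatrix, ValidationError

__all__ = [
    "FPDistConfig",
    "fpdist",
    "std_star",
    "SpecificityResult",
    "summarize_differentials",
    "HostSpecificityModel",
]


@dataclass
class FPDistConfig:
    """Blending weight ``a`` in [0,1] and exponent ``p`` > 0 (default 2)."""

    a: float
    p: float = 2.0

    def __post_init__(self):
        if not 0.0 <= self.a <= 1.0:
            raise ValidationError("weight a must lie in [0, 1]")
        if self.p <= 0:
            raise ValidationError("exponent p must be > 0")


def fpdist(
    pdist: DistanceMatrix, fdist: DistanceMatrix, config: FPDistConfig
) -> DistanceMatrix:
    """Blend scaled phylogenetic and niche distances elementwise."""
    if list(pdist.labels) != list(fdist.labels):
        raise ValidationError("fpdist: label sets/order differ between matrices")
    a, p = config.a, config.p
    # the limits are returned exactly rather than through (x**p)**(1/p)
    if a == 1.0:
        vals = pdist.values.copy()
    elif a == 0.0:
        vals = fdist.values.copy()
    else:
        vals = (a * pdist.values**p + (1.0 - a) * fdist.values**p) ** (1.0 / p)
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(list(pdist.labels), vals, scaled=True)


def std_star(hosts: Sequence[str], distances: DistanceMatrix) -> float:
    """Mean pairwise distance among a parasite's hosts (>= 2 required)."""
    hosts = list(dict.fromkeys(hosts))
    if len(hosts) < 2:
        raise ValidationError("std_star needs at least 2 hosts")
    sub = distances.submatrix(hosts).values
    iu = np.triu_indices(len(hosts), k=1)
    return float(sub[iu].mean())


# ---------------------------------------------------------------------------
# Results container
# ---------------------------------------------------------------------------


@dataclass
class SpecificityResult:
    """Draw-level specificity output for one parasite.

    One row per null iteration: the drawn weight ``alpha``, the dendrogram
    index, observed and expected STD* under that draw, and their difference.
    """

    parasite: str
    n_hosts: int
    alpha: np.ndarray
    dendrogram_id: np.ndarray
    observed: np.ndarray
    expected: np.ndarray

    @property
    def differential(self) -> np.ndarray:
        return self.observed - self.expected

    @property
    def n_iterations(self) -> int:
        return self.alpha.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parasite": self.parasite,
                "iteration": np.arange(self.n_iterations),
                "alpha": self.alpha,
                "dendrogram_id": self.dendrogram_id,
                "observed": self.observed,
                "expected": self.expected,
                "differential": self.differential,
            }
        )

    def summarize(self, n_bins: int = 10) -> pd.DataFrame:
        return summarize_differentials(self, n_bins)

    def significant_overall(self) -> bool:
        """True when the pooled 95% differential interval excludes zero."""
        row = summarize_differentials(self, n_bins=1).iloc[0]
        return bool(row["significant"])

    def plot_differentials(self, n_bins: int = 10, ax=None):
        """Boxplot-style view of differentials across alpha bins."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        summary = self.summarize(n_bins)
        centers = (summary["alpha_low"] + summary["alpha_high"]) / 2
        ax.errorbar(
            centers,
            summary["median"],
            yerr=[summary["median"] - summary["q025"], summary["q975"] - summary["median"]],
            fmt="o",
            capsize=3,
        )
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_xlabel("phylogenetic weight a")
        ax.set_ylabel("STD* differential (observed - expected)")
        ax.set_title(self.parasite)
        return ax


def summarize_differentials(result: SpecificityResult, n_bins: int = 10) -> pd.DataFrame:
    """Per-alpha-bin medians, 2.5/97.5% quantiles, extremes and a
    significance flag (interval excludes zero). Empty bins are flagged,
    never fabricated."""
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(result.alpha, edges[1:-1]), 0, n_bins - 1)
    rows = []
    d = result.differential
    for b in range(n_bins):
        sel = d[which == b]
        row = {"alpha_low": edges[b], "alpha_high": edges[b + 1], "n": int(sel.size)}
        if sel.size == 0:
            row.update(
                median=np.nan, q025=np.nan, q975=np.nan, min=np.nan, max=np.nan,
                significant=False, empty=True,
            )
        else:
            q025, med, q975 = np.quantile(sel, [0.025, 0.5, 0.975])
            row.update(
                median=med, q025=q025, q975=q975, min=sel.min(), max=sel.max(),
                significant=bool(q975 < 0 or q025 > 0), empty=False,
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


class HostSpecificityModel:
    """Permutation-null model of functional-phylogenetic host specificity.

    Parameters
    ----------
    pdist
        Scaled patristic distances over the sampled host pool.
    fdist_ensemble
        Niche distance draws: a list of :class:`Dendrogram` (their scaled
        cophenetic matrices are used) or of scaled :class:`DistanceMatrix`.
    pool
        The sampled host species pool from which null hosts are drawn;
        defaults to the matrix labels.
    """

    def __init__(
        self,
        pdist: DistanceMatrix,
        fdist_ensemble: Sequence,
        pool: Sequence[str] | None = None,
    ):
        self.pool = sorted(pool) if pool is not None else list(pdist.labels)
        self.pdist = pdist.submatrix(self.pool)
        mats = []
        for f in fdist_ensemble:
            dm = f.cophenetic if isinstance(f, Dendrogram) else f
            mats.append(dm.submatrix(self.pool).values)
        if not mats:
            raise ValidationError("empty niche ensemble")
        self.fdist = mats
        self._index = {s: i for i, s in enumerate(self.pool)}

    def fit(
        self,
        hosts: Sequence[str],
        parasite: str = "parasite",
        config: AnalysisConfig | None = None,
        rng: np.random.Generator | None = None,
    ) -> SpecificityResult:
        """Run the permutation null for one parasite's observed host set.

        Each iteration draws ``a ~ U(0,1)`` and one dendrogram; observed and
        expected STD* share both draws so the differential isolates host
        identity. When ``config.subsample_size`` is set and the parasite has
        more hosts, a fresh subsample of observed hosts is taken per
        iteration (the device used for the many-host cat flea).
        """
        config = config or AnalysisConfig()
        if rng is None:
            rng = np.random.default_rng(config.seed)
        hosts = sorted(dict.fromkeys(hosts))
        unknown = [h for h in hosts if h not in self._index]
        if unknown:
            raise ValidationError(f"hosts not in pool: {unknown}")
        if len(hosts) < 2:
            raise ValidationError("need >= 2 observed hosts")
        k = config.subsample_size
        if k is not None and k > len(hosts):
            raise ValidationError(
                f"subsample_size {k} exceeds observed host count {len(hosts)}"
            )
        draw_size = k if (k is not None and k < len(hosts)) else len(hosts)
        if draw_size >= len(self.pool):
            raise ValidationError("host set must be smaller than the pool")

        n_iter = config.n_null_iterations
        p = config.p_exponent
        host_ix = np.array([self._index[h] for h in hosts])
        npool = len(self.pool)
        Pp = self.pdist.values**p
        Fp = [f**p for f in self.fdist]
        iu = np.triu_indices(draw_size, k=1)

        if config.alpha_mode == "grid":
            alphas = np.linspace(0.0, 1.0, n_iter)
        else:
            alphas = rng.uniform(0.0, 1.0, size=n_iter)
        dendro = rng.integers(0, len(Fp), size=n_iter)
        observed = np.empty(n_iter)
        expected = np.empty(n_iter)
        inv_p = 1.0 / p

        for t in range(n_iter):
            a = alphas[t]
            Fd = Fp[dendro[t]]
            if draw_size < len(hosts):
                obs_ix = rng.choice(host_ix, size=draw_size, replace=False)
            else:
                obs_ix = host_ix
            null_ix = rng.choice(npool, size=draw_size, replace=False)
            sub = a * Pp[np.ix_(obs_ix, obs_ix)] + (1 - a) * Fd[np.ix_(obs_ix, obs_ix)]
            observed[t] = (sub[iu] ** inv_p).mean()
            sub = a * Pp[np.ix_(null_ix, null_ix)] + (1 - a) * Fd[np.ix_(null_ix, null_ix)]
            expected[t] = (sub[iu] ** inv_p).mean()

        return SpecificityResult(
            parasite=parasite,
            n_hosts=len(hosts),
            alpha=alphas,
            dendrogram_id=dendro,
            observed=observed,
            expected=expected,
        )
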