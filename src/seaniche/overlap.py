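"""Directional environmental niche overlap between two suitability surfaces.

A habitat-suitability surface is converted to a probability distribution
over the grid by dividing each cell value n_j by the total N = sum_j n_j.
The specific overlap of species i onto species k is

    SO_ik = exp( sum_j p_ij ln p_kj  -  sum_j p_ij ln p_ij )
          = exp( -KL(p_i || p_k) )

i.e. the exponential of the negative Kullback-Leibler divergence: the
probability of obtaining species i's utilisation distribution from species
k's.  The index is directional (SO_ik != SO_ki in general) and lies in
(0, 1], reaching 1 iff the distributions coincide.  The null hypothesis of
complete overlap (SO_ik = 1) is tested with

    U_ik = -2 N_i ln SO_ik  ~  chi-square with r - 1 degrees of freedom,

where r is the number of cells carrying suitability scores and N_i is, by
default, species i's pre-normalisation suitability sum (an override allows
using the presence-locality count instead).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .grids import Raster

__all__ = ["SuitabilitySurface", "ProbabilitySurface", "OverlapResult",
           "normalize_surface", "specific_overlap", "u_test",
           "overlap_report"]


@dataclass
class SuitabilitySurface:
    """Per-cell suitability scores n_j on a masked grid."""

    raster: Raster

    @property
    def r(self) -> int:
        """Number of cells carrying suitability scores."""
        return self.raster.grid.n_valid

    @property
    def N(self) -> float:
        """Sum of all cell values; the N_i of the U statistic."""
        return float(self.raster.valid_values().sum())

    def restricted_to(self, mask: np.ndarray) -> "SuitabilitySurface":
        return SuitabilitySurface(self.raster.masked_like(mask))


@dataclass
class ProbabilitySurface:
    """A suitability surface normalised to sum 1 over its r cells."""

    p: np.ndarray       # (r,) probabilities over valid cells, row-major
    r: int
    N: float            # the pre-normalisation total

    def __post_init__(self):
        if np.any(self.p < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(self.p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")


@dataclass
class OverlapResult:
    """SO_ik with its chi-square test."""

    so: float
    u: float
    df: int
    p_value: float
    n_i: float
    support_mismatch: bool = False


def normalize_surface(s: SuitabilitySurface) -> ProbabilitySurface:
    """p_j = n_j / N over the r valid cells; N is retained for the U test."""
    vals = s.raster.valid_values()
    if len(vals) == 0:
        raise ValueError("surface has no valid cells")
    if np.any(vals < 0):
        raise ValueError("suitability scores must be non-negative")
    total = vals.sum()
    if total <= 0:
        raise ValueError("surface is zero everywhere; cannot normalise")
    p = vals / total
    p = p / p.sum()  # kill residual round-off so sum(p) == 1 exactly enough
    return ProbabilitySurface(p=p, r=len(vals), N=float(total))


def specific_overlap(p_i: ProbabilitySurface, p_k: ProbabilitySurface) -> float:
    """SO_ik = exp(sum p_ij ln p_kj - sum p_ij ln p_ij), cells with
    p_ij = 0 excluded from both sums (0 ln 0 := 0).

    Computed in the log domain.  If p_k is zero somewhere p_i is positive,
    the overlap is exactly 0 (support mismatch).
    """
    if p_i.r != p_k.r:
        raise ValueError(f"surfaces disagree on r: {p_i.r} != {p_k.r}")
    a, b = p_i.p, p_k.p
    supp = a > 0
    if np.any(b[supp] == 0):
        return 0.0
    log_term = a[supp] @ (np.log(b[supp]) - np.log(a[supp]))  # -KL(a||b)
    return float(min(np.exp(log_term), 1.0))


def u_test(so: float, n_i: float, r: int) -> OverlapResult:
    """U = -2 N_i ln SO_ik referred to chi-square with r - 1 df.

    SO = 1 gives U = 0 and p = 1.  SO = 0 gives U = +inf with the p-value
    reported as 0 and a support-mismatch flag.
    """
    if n_i <= 0:
        raise ValueError("N_i must be positive")
    if r < 2:
        raise ValueError("need r >= 2 cells for the test")
    if so < 0 or so > 1:
        raise ValueError("SO must lie in [0, 1]")
    df = r - 1
    if so == 0.0:
        return OverlapResult(so=0.0, u=np.inf, df=df, p_value=0.0, n_i=n_i,
                             support_mismatch=True)
    u = -2.0 * n_i * np.log(so)
    p_value = float(chi2.sf(u, df))
    return OverlapResult(so=float(so), u=float(u), df=df, p_value=p_value,
                         n_i=float(n_i))


def _shared_support(si: SuitabilitySurface, sk: SuitabilitySurface):
    gi, gk = si.raster.grid, sk.raster.grid
    if not gi.same_geometry(gk):
        raise ValueError("surfaces are on different grid geometries")
    common = gi.mask & gk.mask
    if not common.any():
        raise ValueError("surfaces share no valid cells")
    return si.restricted_to(common), sk.restricted_to(common)


def pairwise_overlap(si: SuitabilitySurface, sk: SuitabilitySurface,
                     n_i_mode: str = "suitability_sum",
                     n_localities: int | None = None) -> OverlapResult:
    """SO_ik and its U test for species i onto species k.

    The two surfaces are first intersected to their common valid-cell set
    (one shared r).  ``n_i_mode`` selects N_i: the pre-normalisation
    suitability sum of species i (default) or ``"n_localities"`` to use a
    presence-locality count supplied via ``n_localities``.
    """
    si_c, sk_c = _shared_support(si, sk)
    pi = normalize_surface(si_c)
    pk = normalize_surface(sk_c)
    so = specific_overlap(pi, pk)
    if n_i_mode == "suitability_sum":
        n_i = pi.N
    elif n_i_mode == "n_localities":
        if n_localities is None:
            raise ValueError("n_localities mode needs an explicit count")
        n_i = float(n_localities)
    else:
        raise ValueError(f"unknown n_i_mode {n_i_mode!r}")
    return u_test(so, n_i, pi.r)


def overlap_report(surfaces: dict[tuple[str, str], SuitabilitySurface],
                   n_i_mode: str = "suitability_sum",
                   locality_counts: dict[tuple[str, str], int] | None = None
                   ) -> pd.DataFrame:
    """Both-direction overlap table over species pairs within each season.

    ``surfaces`` maps (species, season) to a suitability surface.  Missing
    surfaces simply restrict the report (partial output).  Columns: i, k,
    season, SO_ik, U, df, P.
    """
    seasons = sorted({season for (_, season) in surfaces})
    rows = []
    for season in seasons:
        species = sorted({sp for (sp, se) in surfaces if se == season})
        for i in species:
            for k in species:
                if i == k:
                    continue
                n_loc = (locality_counts or {}).get((i, season))
                res = pairwise_overlap(surfaces[(i, season)],
                                       surfaces[(k, season)],
                                       n_i_mode=n_i_mode, n_localities=n_loc)
                rows.append({"i": i, "k": k, "season": season,
                             "SO_ik": res.so, "U": res.u, "df": res.df,
                             "P": res.p_value})
    return pd.DataFrame(rows, columns=["i", "k", "season", "SO_ik", "U",
                                       "df", "P"])
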