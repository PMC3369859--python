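"""Founder-age estimation from haplotype trees: rho, sigma, and time scales.

The age of a clade is estimated from the averaged distance (rho) of its
haplotypes to the clade's root haplotype: rho is the multiplicity-weighted
mean number of qualifying substitutions on the root-to-tip path, counted by
default over the coding region (nps 364-15791, 15,428 bp) with indels and
control-region changes excluded.  Time is obtained by multiplying by a
calibrated substitution rate, 3,172 years per substitution over the whole
coding region.

The standard error of rho uses the branch-weighted heuristic

    sigma^2 = n^-2 * sum_e  l_e * m_e^2

where, for each edge e inside the clade, l_e is the number of qualifying
mutations on e and m_e is the (multiplicity-weighted) number of clade tips
below it.  For a star tree with unit terminal branches this reduces to
sqrt(rho / n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import pandas as pd

from .classifier import round_half_up
from .parsimony_tree import AnnotatedTree, CladeError, TreeNode, root_distance
from .reference_variants import CODING_REGION, Region

__all__ = [
    "CladeStats",
    "rho",
    "sigma",
    "time_from_rho",
    "time_from_divergence",
    "clade_stats",
    "stats_table",
    "published_clade_ages",
    "RATE_YEARS_PER_SUB",
    "CODING_SITES",
]

RATE_YEARS_PER_SUB = 3172.0
CODING_SITES = 15428


def rho(
    tree: AnnotatedTree,
    clade_root: Optional[TreeNode] = None,
    region: Optional[Region] = CODING_REGION,
    substitutions_only: bool = True,
) -> float:
    """Multiplicity-weighted mean root-to-tip distance within a clade."""
    clade_root = clade_root or tree.root
    tips = tree.tips(clade_root)
    n = sum(t.multiplicity for t in tips)
    if n == 0:
        raise CladeError(f"clade at {clade_root.name!r} has no tips")
    total = sum(
        t.multiplicity * root_distance(tree, t, clade_root, region, substitutions_only)
        for t in tips
    )
    return total / n


def sigma(
    tree: AnnotatedTree,
    clade_root: Optional[TreeNode] = None,
    region: Optional[Region] = CODING_REGION,
    substitutions_only: bool = True,
) -> float:
    """Heuristic standard error of rho (branch-weighted)."""
    clade_root = clade_root or tree.root
    n = tree.n_tips(clade_root)
    if n == 0:
        raise CladeError(f"clade at {clade_root.name!r} has no tips")
    acc = 0.0
    for node in tree.walk(clade_root):
        if node is clade_root:
            continue
        l_e = 0
        for m in node.edge_mutations:
            if substitutions_only and not m.call.kind.is_substitution:
                continue
            if region is not None and m.position not in region:
                continue
            l_e += 1
        if l_e == 0:
            continue
        m_e = tree.n_tips(node)  # multiplicity-weighted tips below this edge
        acc += l_e * m_e ** 2
    return math.sqrt(acc) / n


def time_from_rho(rho_value: float, rate_years_per_sub: float = RATE_YEARS_PER_SUB) -> float:
    """Convert a substitution count to an age in thousand years (ka)."""
    if rho_value < 0:
        raise ValueError("rho must be non-negative")
    return rho_value * rate_years_per_sub / 1000.0


def time_from_divergence(
    subs_per_site: float,
    n_sites: int = CODING_SITES,
    rate_years_per_sub: float = RATE_YEARS_PER_SUB,
) -> float:
    """Convert a per-site divergence to an age in ka.

    ``subs_per_site * n_sites`` recovers the substitution count for the
    region, which the per-substitution rate then converts to years.  Note
    that applying this to a divergence value already rounded to 5 decimals
    can differ from an age computed upstream of rounding (e.g. 0.00026 over
    the coding region gives 12.72 ka, not the 12.5 ka obtained from the
    unrounded estimate it was printed from).
    """
    if subs_per_site < 0:
        raise ValueError("divergence must be non-negative")
    return subs_per_site * n_sites * rate_years_per_sub / 1000.0


@dataclass
class CladeStats:
    """Age statistics for one clade, mirroring a survey-style results row."""

    clade_name: str
    n_tips: int
    rho: float
    sigma: float
    T_ka: float
    dT_ka: float
    rate_years_per_sub: float = RATE_YEARS_PER_SUB
    region: Region = CODING_REGION
    subs_per_site: Optional[float] = None
    se_subs_per_site: Optional[float] = None
    n_sites: int = CODING_SITES

    @property
    def T_ml_ka(self) -> Optional[float]:
        if self.subs_per_site is None:
            return None
        return time_from_divergence(self.subs_per_site, self.n_sites, self.rate_years_per_sub)


def clade_stats(
    tree: AnnotatedTree,
    clade_root: Optional[TreeNode] = None,
    clade_name: str = "clade",
    region: Optional[Region] = CODING_REGION,
    rate_years_per_sub: float = RATE_YEARS_PER_SUB,
    substitutions_only: bool = True,
) -> CladeStats:
    clade_root = clade_root or tree.root
    r = rho(tree, clade_root, region, substitutions_only)
    s = sigma(tree, clade_root, region, substitutions_only)
    return CladeStats(
        clade_name=clade_name,
        n_tips=tree.n_tips(clade_root),
        rho=round(r, 3),
        sigma=round(s, 3),
        T_ka=round_half_up(time_from_rho(r, rate_years_per_sub), 1),
        dT_ka=round_half_up(time_from_rho(s, rate_years_per_sub), 1),
        rate_years_per_sub=rate_years_per_sub,
        region=region if region is not None else Region(1, 1),
    )


def stats_table(stats: Sequence[CladeStats]) -> pd.DataFrame:
    rows = []
    for st in stats:
        rows.append(
            {
                "clade": st.clade_name,
                "n_mtdnas": st.n_tips,
                "rho": round_half_up(st.rho, 3),
                "sigma": round_half_up(st.sigma, 3),
                "T_ka": st.T_ka,
                "dT_ka": st.dT_ka,
                "subs_per_site": st.subs_per_site,
                "T_ml_ka": None if st.T_ml_ka is None else round_half_up(st.T_ml_ka, 1),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["clade", "n_mtdnas", "rho", "sigma", "T_ka", "dT_ka", "subs_per_site", "T_ml_ka"],
    )


def published_clade_ages() -> pd.DataFrame:
    """The shipped regression table of printed clade ages (rho, sigma, T)."""
    ref = resources.files("bovmito.data").joinpath("t1_clade_ages.tsv")
    with ref.open() as fh:
        return pd.read_csv(fh, sep="\t")
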