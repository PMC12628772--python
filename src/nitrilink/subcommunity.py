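"""Delineate the nitrifier guild and its association-filtered subcommunities.

A taxon joins the nitrifier subcommunity when it carries a predicted
nitrification gene (amo or nxr) AND is classified in a known nitrifier
genus.  Non-nitrifier taxa join the nitrifier-associated subcommunity at a
given cutoff when they have at least one sufficiently strong, significant
network edge to any nitrifier; the "core" set at a cutoff is the
intersection of the two periods' sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .sparcc import AssociationNetwork

log = logging.getLogger("nitrilink")

#: Genera accepted as nitrifiers: ammonia oxidizers then nitrite oxidizers.
DEFAULT_NITRIFIER_GENERA = frozenset(
    {
        "Nitrosomonas", "Nitrosospira", "Nitrosovibrio", "Nitrosolobus",
        "Nitrosococcus",
        "Nitrobacter", "Nitrotoga", "Nitrococcus", "Nitrospira",
        "Nitrospina", "Nitrolancea", "Ca. Nitromaritima",
    }
)


@dataclass(frozen=True)
class SubcommunitySet:
    """A named taxon subset with its provenance."""

    name: str
    taxa: frozenset
    provenance: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.taxa)

    def __contains__(self, taxon):
        return taxon in self.taxa


def select_nitrifiers(
    annotation: pd.DataFrame, genera=DEFAULT_NITRIFIER_GENERA
) -> SubcommunitySet:
    """Taxa with (amo OR nxr) gene flags AND a known nitrifier genus."""
    for col in ("genus", "amo", "nxr"):
        if col not in annotation.columns:
            raise ValueError(f"annotation missing column {col!r}")
    flags = annotation["amo"].astype(bool) | annotation["nxr"].astype(bool)
    lineage_ok = annotation["genus"].isin(genera)
    selected = frozenset(annotation.index[flags & lineage_ok])
    if not selected:
        log.warning("no taxa satisfied both nitrifier criteria")
    return SubcommunitySet(
        "nitrifier", selected, {"criteria": "gene flag AND genus list"}
    )


def associated_subcommunity(
    network: AssociationNetwork,
    nitrifiers: SubcommunitySet,
    cutoff: float,
    alpha: float = 0.01,
    absolute: bool = True,
    period=None,
) -> SubcommunitySet:
    """Non-nitrifier taxa with a significant edge to any nitrifier.

    A taxon qualifies when |rho| > cutoff (or rho > cutoff with
    ``absolute=False``) and p < alpha for at least one nitrifier partner.
    May legitimately be empty at high cutoffs.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie in (0, 1)")
    anchors = [t for t in network.taxa if t in nitrifiers]
    members = set()
    if anchors:
        rho = network.rho.loc[:, anchors]
        strength = rho.abs() if absolute else rho
        ok = (strength > cutoff) & (network.pvalues.loc[:, anchors] < alpha)
        members = set(ok.index[ok.any(axis=1)]) - set(nitrifiers.taxa)
    return SubcommunitySet(
        f"associated_c{cutoff:g}",
        frozenset(members),
        {
            "anchor": frozenset(anchors),
            "cutoff": cutoff,
            "alpha": alpha,
            "period": period,
        },
    )


def cutoff_sweep(
    network: AssociationNetwork,
    nitrifiers: SubcommunitySet,
    cutoffs=tuple(round(0.1 * k, 1) for k in range(1, 10)),
    alpha: float = 0.01,
    absolute: bool = True,
    period=None,
) -> dict:
    """Associated subcommunity per cutoff; sets are nested along the sweep."""
    cutoffs = list(cutoffs)
    if cutoffs != sorted(cutoffs):
        raise ValueError("cutoffs must be sorted ascending")
    return {
        c: associated_subcommunity(
            network, nitrifiers, c, alpha=alpha, absolute=absolute,
            period=period,
        )
        for c in cutoffs
    }


def core_subcommunity(sets_p1: dict, sets_p2: dict) -> dict:
    """Per-cutoff intersection of the two periods' associated sets."""
    if set(sets_p1) != set(sets_p2):
        raise ValueError("the two periods must share the same cutoff grid")
    out = {}
    for c in sorted(sets_p1):
        taxa = sets_p1[c].taxa & sets_p2[c].taxa
        out[c] = SubcommunitySet(
            f"core_c{c:g}",
            frozenset(taxa),
            {"cutoff": c, "period": "core"},
        )
    return out


def subset_table(counts: pd.DataFrame, subset: SubcommunitySet) -> pd.DataFrame:
    """Restrict a count table's columns to a subcommunity (samples kept)."""
    unknown = sorted(subset.taxa - set(counts.columns))
    if unknown:
        raise ValueError(f"subcommunity taxa absent from table: {unknown}")
    cols = [t for t in counts.columns if t in subset.taxa]
    if not cols:
        log.warning("subcommunity %r is empty; returning a zero-column table",
                    subset.name)
    return counts.loc[:, cols]


def membership_frame(sweeps: dict) -> pd.DataFrame:
    """Long-format membership table: one row per (taxon, cutoff, period).

    ``sweeps`` maps a period label to a {cutoff: SubcommunitySet} mapping.
    """
    rows = []
    for period, sets in sweeps.items():
        for cutoff, sub in sorted(sets.items()):
            for taxon in sorted(sub.taxa):
                rows.append((taxon, sub.name, cutoff, period))
    return pd.DataFrame(
        rows, columns=["taxon_id", "set_name", "cutoff", "period"]
    )
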