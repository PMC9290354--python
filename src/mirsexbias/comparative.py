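"""Comparative genomics of microRNA loci: genomic clustering, cluster
representatives, inter-element translocation detection, and cross-species
pairing of sex-bias fold-changes.

Clustered microRNAs tend to be co-transcribed, so cluster-level analyses keep
only the highest-expressed member within 10 kb single-linkage clusters.
Translocations are judged on Muller element letters, which are robust to arm
renaming between karyotypes (XL/XR map to elements A/D).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .homology import HomologyGroup
from .io_tables import MirnaLocus

__all__ = [
    "MirnaCluster",
    "TranslocationReport",
    "call_clusters",
    "select_representative",
    "detect_translocations",
    "pair_ortholog_bias",
    "DEFAULT_CLUSTER_GAP",
]

DEFAULT_CLUSTER_GAP = 10_000


@dataclass(frozen=True)
class MirnaCluster:
    """A run of same-chromosome loci whose consecutive gaps stay within the
    clustering distance; ``representative`` is filled by
    :func:`select_representative`."""

    species: str
    chromosome: str
    members: tuple[str, ...]
    representative: str | None = None


def call_clusters(
    loci: Sequence[MirnaLocus], gap_bp: int = DEFAULT_CLUSTER_GAP
) -> list[MirnaCluster]:
    """Single-linkage genomic clustering of one species' loci.

    Two loci join a cluster when a chain of loci connects them with
    inter-interval gaps <= ``gap_bp`` (gap = max(0, next.start - prev.end -
    1); the boundary is inclusive, the most permissive reading of "within
    10 kb").  Sorting loci by interval start within each chromosome makes the
    chain condition equivalent to consecutive-gap thresholding.
    """
    if not loci:
        return []
    species = {l.species for l in loci}
    if len(species) != 1:
        raise ValueError("call_clusters expects loci of a single species")
    out: list[MirnaCluster] = []
    by_chrom: dict[str, list[MirnaLocus]] = {}
    for l in loci:
        by_chrom.setdefault(l.chromosome, []).append(l)
    for chrom in sorted(by_chrom):
        block = sorted(by_chrom[chrom], key=lambda l: (l.start, l.end, l.id))
        current = [block[0]]
        max_end = block[0].end
        for l in block[1:]:
            gap = max(0, l.start - max_end - 1)
            if gap <= gap_bp:
                current.append(l)
            else:
                out.append(
                    MirnaCluster(l.species, chrom, tuple(x.id for x in current))
                )
                current = [l]
            max_end = max(max_end, l.end)
        out.append(
            MirnaCluster(current[0].species, chrom, tuple(x.id for x in current))
        )
    return out


def select_representative(
    cluster: MirnaCluster, base_mean: Mapping[str, float]
) -> MirnaCluster:
    """The highest-expressed member (largest base mean) represents the
    cluster; ties break to the lexicographically smallest id."""
    known = [m for m in cluster.members if m in base_mean and pd.notna(base_mean[m])]
    if not known:
        raise ValueError(
            f"no expression value for any member of cluster {cluster.members}"
        )
    rep = min(known, key=lambda m: (-float(base_mean[m]), m))
    return MirnaCluster(cluster.species, cluster.chromosome, cluster.members, rep)


@dataclass(frozen=True)
class TranslocationReport:
    """Concordance of Muller elements across ortholog pairs."""

    n_pairs: int
    n_concordant: int
    discordant: tuple[tuple[str, str, str, str], ...]  # id1, id2, muller1, muller2
    n_unknown: int = 0

    def __post_init__(self) -> None:
        if self.n_concordant + len(self.discordant) != self.n_pairs:
            raise ValueError("concordant + discordant must equal pairs examined")


def detect_translocations(orthologs: pd.DataFrame) -> TranslocationReport:
    """Count ortholog pairs whose Muller element letters differ.

    Pairs with an unknown element on either side are excluded from the
    comparison and counted separately.  The report is symmetric in species
    order.
    """
    required = {"id1", "id2", "muller1", "muller2"}
    if not required <= set(orthologs.columns):
        raise ValueError(f"ortholog table needs columns {sorted(required)}")
    known = orthologs[
        orthologs["muller1"].ne("unknown") & orthologs["muller2"].ne("unknown")
    ]
    disc = known[known["muller1"] != known["muller2"]]
    discordant = tuple(
        (r.id1, r.id2, r.muller1, r.muller2)
        for r in disc.sort_values(["id1", "id2"]).itertuples()
    )
    return TranslocationReport(
        n_pairs=len(known),
        n_concordant=len(known) - len(discordant),
        discordant=discordant,
        n_unknown=len(orthologs) - len(known),
    )


def pair_ortholog_bias(
    groups: Iterable[HomologyGroup],
    dge1: pd.DataFrame,
    dge2: pd.DataFrame,
    annotation2: Sequence[MirnaLocus],
    neo_x_element: str = "D",
    x_elements: Sequence[str] = ("A", "D"),
) -> pd.DataFrame:
    """Pair one-to-one orthologs' log2 fold-changes across species.

    Only one-to-one groups whose members carry fold-change estimates in both
    species (i.e. passed the expression filter) are admitted.  Each pair is
    stratified by the species-2 chromosome class: the neo-X element, another
    X-linked element, or an autosome; the species-2 age class is carried
    along for the age-by-chromosome rank tests.
    """
    ann = {l.id: l for l in annotation2}
    rows = []
    for g in groups:
        if g.cls != "one_to_one":
            continue
        id1, id2 = g.members1[0], g.members2[0]
        if id1 not in dge1.index or id2 not in dge2.index:
            continue
        fc1 = dge1.at[id1, "log2fc"]
        fc2 = dge2.at[id2, "log2fc"]
        if pd.isna(fc1) or pd.isna(fc2):
            continue
        loc2 = ann.get(id2)
        if loc2 is None:
            continue
        if loc2.muller == neo_x_element:
            chrom_class = "neo-X"
        elif loc2.muller in x_elements:
            chrom_class = "X"
        else:
            chrom_class = "autosome"
        rows.append(
            {
                "id1": id1,
                "id2": id2,
                "log2fc1": float(fc1),
                "log2fc2": float(fc2),
                "chrom_class": chrom_class,
                "age_class": loc2.age_class,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["id1", "id2", "log2fc1", "log2fc2", "chrom_class", "age_class"],
    )
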