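"""End-to-end orchestration: simulate -> DGE -> homology -> clusters ->
synteny -> rank tests -> report.

Every stage is deterministic given ``PipelineConfig.sim.seed``; rerunning the
same configuration produces byte-identical output files.  Species 1 plays the
role of the reference species with unpaired public male/female datasets;
species 2 is the focal species with paired (batch-controlled) samples and a
gonad (testis/ovary) experiment.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from . import comparative, expression, homology, io_tables
from .align import Scoring
from .simulate import (
    GroundTruth,
    SimulationConfig,
    simulate_annotation,
    simulate_counts,
    simulate_sequences,
)
from .stats import SrhResult, linear_fit, scheirer_ray_hare

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds of the analysis, defaulting to the study's values:
    FDR 0.10 (with a stricter 0.05 variant reported alongside), minimum
    fold-change 1.25, pairing search at word size 10 / E <= 0.1, genome-scan
    filters E <= 0.01 with alignment length >= 60, and 10-kb clustering."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    design: Literal["paired", "unpaired"] = "paired"
    norm: Literal["mor", "tmm"] = "mor"
    fdr: float = 0.10
    fdr_strict: float = 0.05
    min_fc: float = 1.25
    word_size: int = 10
    evalue_pairing: float = 0.1
    evalue_scan: float = 0.01
    min_aln_len: int = 60
    cluster_gap: int = 10_000
    scoring: Scoring = field(default_factory=Scoring)
    ortholog_overrides: tuple[tuple[str, str], ...] = ()
    with_gonad: bool = True
    build_trees: bool = True

    def __post_init__(self) -> None:
        for name in (
            "fdr", "fdr_strict", "min_fc", "evalue_pairing", "evalue_scan",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.word_size < 4 or self.cluster_gap <= 0 or self.min_aln_len <= 0:
            raise ValueError("invalid threshold configuration")


@dataclass
class PipelineResult:
    annotation1: list
    annotation2: list
    truth: GroundTruth
    dge1: pd.DataFrame
    dge2: pd.DataFrame
    dge_gonad: pd.DataFrame | None
    groups: list
    clusters1: list
    clusters2: list
    orthologs: pd.DataFrame
    translocations: comparative.TranslocationReport
    bias_pairs: pd.DataFrame
    srh_whole: SrhResult
    srh_gonad: SrhResult | None
    summary: dict


def _ortholog_table(groups, ann1, ann2) -> pd.DataFrame:
    a1 = {l.id: l for l in ann1}
    a2 = {l.id: l for l in ann2}
    rows = []
    for g in groups:
        if g.cls not in ("one_to_one", "one_to_many"):
            continue
        for id1 in g.members1:
            for id2 in g.members2:
                l1, l2 = a1[id1], a2[id2]
                rows.append(
                    {
                        "id1": id1,
                        "id2": id2,
                        "muller1": l1.muller,
                        "muller2": l2.muller,
                        "chromosome1": l1.chromosome,
                        "start1": l1.start,
                        "end1": l1.end,
                        "chromosome2": l2.chromosome,
                        "start2": l2.start,
                        "end2": l2.end,
                    }
                )
    return pd.DataFrame(
        rows, columns=io_tables._ORTHO_COLS
    ).sort_values(["id1", "id2"]).reset_index(drop=True)


def _bias_counts(dge: pd.DataFrame, fdr: float, min_fc: float) -> dict:
    calls = expression.call_sex_biased(dge.dropna(subset=["q"]), fdr, min_fc)
    return {
        "male": int((calls == "male").sum()),
        "female": int((calls == "female").sum()),
    }


def _srh_table(dge: pd.DataFrame, annotation, x_elements) -> tuple[pd.DataFrame, SrhResult]:
    ann = {l.id: l for l in annotation}
    sub = dge.dropna(subset=["log2fc"])
    rows = [
        {
            "locus": i,
            "log2fc": float(sub.at[i, "log2fc"]),
            "chromosome": "X" if ann[i].muller in x_elements else "autosome",
            "age": ann[i].age_class,
        }
        for i in sub.index
        if i in ann
    ]
    table = pd.DataFrame(rows, columns=["locus", "log2fc", "chromosome", "age"])
    res = scheirer_ray_hare(
        table["log2fc"], table["age"], table["chromosome"],
        names=("age", "chromosome"),
    )
    return table, res


def run_pipeline(config: PipelineConfig, outdir=None) -> PipelineResult:
    """Run every stage on a simulated two-species study; optionally write the
    per-stage TSVs, a JSON summary and a parameter manifest under ``outdir``."""
    sim = config.sim
    ann1, ann2, truth = simulate_annotation(sim)
    seqs1, seqs2 = simulate_sequences(ann1, ann2, truth, sim)
    counts1 = simulate_counts(ann1, truth, sim, design="unpaired", mode="whole")
    counts2 = simulate_counts(ann2, truth, sim, design=config.design, mode="whole")

    dge1 = expression.sex_bias_analysis(
        counts1, design="unpaired", norm=config.norm,
        fdr=config.fdr, min_fc=config.min_fc,
    )
    dge2 = expression.sex_bias_analysis(
        counts2, design=config.design, norm=config.norm,
        fdr=config.fdr, min_fc=config.min_fc,
    )
    dge_gonad = None
    if config.with_gonad:
        gonad = simulate_counts(ann2, truth, sim, design=config.design, mode="gonad")
        dge_gonad = expression.sex_bias_analysis(
            gonad, design=config.design, norm=config.norm,
            fdr=config.fdr, min_fc=config.min_fc,
        )

    hits = homology.find_hits(
        seqs1, seqs2, config.scoring,
        word_size=config.word_size, evalue_max=config.evalue_pairing,
    )
    groups = homology.build_groups(
        hits, [l.id for l in ann1], [l.id for l in ann2],
        overrides=config.ortholog_overrides,
    )
    if config.build_trees:
        seqs = {**seqs1, **seqs2}
        with_trees = []
        for g in groups:
            members = g.members1 + g.members2
            if len(members) >= 3:
                dm = homology.distance_matrix(
                    {m: seqs[m] for m in members}, config.scoring
                )
                nwk = io_tables.write_newick(homology.neighbor_joining(dm))
                g = homology.HomologyGroup(g.members1, g.members2, g.cls, nwk)
            with_trees.append(g)
        groups = with_trees

    bm1 = dge1["base_mean"].to_dict()
    bm2 = dge2["base_mean"].to_dict()
    clusters1 = [
        comparative.select_representative(c, bm1)
        for c in comparative.call_clusters(ann1, config.cluster_gap)
    ]
    clusters2 = [
        comparative.select_representative(c, bm2)
        for c in comparative.call_clusters(ann2, config.cluster_gap)
    ]

    orthologs = _ortholog_table(groups, ann1, ann2)
    translocations = comparative.detect_translocations(orthologs)

    bias_pairs = comparative.pair_ortholog_bias(
        groups, dge1, dge2, ann2,
        neo_x_element=sim.muller.neo_x, x_elements=sim.muller.x_linked(2),
    )
    fits = {}
    for label, mask in (
        ("neo_x", bias_pairs["chrom_class"] == "neo-X"),
        ("autosome", bias_pairs["chrom_class"] == "autosome"),
    ):
        sub = bias_pairs[mask]
        if len(sub) >= 3 and np.ptp(sub["log2fc1"].to_numpy()) > 0:
            fit = linear_fit(sub["log2fc1"], sub["log2fc2"])
            fits[label] = {
                "slope": fit.slope, "intercept": fit.intercept,
                "r_squared": fit.r_squared, "p": fit.p, "n": fit.n,
            }

    srh_table, srh_whole = _srh_table(dge2, ann2, sim.muller.x_linked(2))
    srh_gonad = None
    if dge_gonad is not None:
        _, srh_gonad = _srh_table(dge_gonad, ann2, sim.muller.x_linked(2))

    def srh_dict(res: SrhResult | None) -> dict | None:
        if res is None:
            return None
        return {
            name: {"H": t.H, "df": t.df, "p": t.p}
            for name, t in res.effects.items()
        }

    summary = {
        "seed": sim.seed,
        "n_loci_sp1": len(ann1),
        "n_loci_sp2": len(ann2),
        "biased_sp1": _bias_counts(dge1, config.fdr, config.min_fc),
        "biased_sp2": _bias_counts(dge2, config.fdr, config.min_fc),
        "biased_sp2_strict": _bias_counts(dge2, config.fdr_strict, config.min_fc),
        "homology_group_classes": {
            cls: sum(g.cls == cls for g in groups)
            for cls in ("one_to_one", "one_to_many", "many_to_many", "unpaired")
        },
        "translocations": {
            "pairs_examined": translocations.n_pairs,
            "concordant": translocations.n_concordant,
            "discordant": [list(t) for t in translocations.discordant],
        },
        "planted_translocations": len(truth.translocations),
        "clusters_sp1": len(clusters1),
        "clusters_sp2": len(clusters2),
        "bias_conservation_fits": fits,
        "srh_whole": srh_dict(srh_whole),
        "srh_gonad": srh_dict(srh_gonad),
    }

    result = PipelineResult(
        annotation1=ann1, annotation2=ann2, truth=truth,
        dge1=dge1, dge2=dge2, dge_gonad=dge_gonad,
        groups=groups, clusters1=clusters1, clusters2=clusters2,
        orthologs=orthologs, translocations=translocations,
        bias_pairs=bias_pairs, srh_whole=srh_whole, srh_gonad=srh_gonad,
        summary=summary,
    )
    if outdir is not None:
        _write_bundle(result, config, Path(outdir))
    return result


def _frame_groups(groups) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "members1": ",".join(g.members1),
                "members2": ",".join(g.members2),
                "class": g.cls,
                "tree": g.tree_newick or "",
            }
            for g in groups
        ],
        columns=["members1", "members2", "class", "tree"],
    )


def _frame_clusters(clusters) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": c.species,
                "chromosome": c.chromosome,
                "members": ",".join(c.members),
                "representative": c.representative or "",
            }
            for c in clusters
        ],
        columns=["species", "chromosome", "members", "representative"],
    )


def _write_bundle(result: PipelineResult, config: PipelineConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    ff = "%.10g"

    def w(frame: pd.DataFrame, name: str, index=False) -> None:
        frame.to_csv(outdir / name, sep="\t", index=index, float_format=ff)

    w(result.dge1, "dge_sp1.tsv", index=True)
    w(result.dge2, "dge_sp2.tsv", index=True)
    if result.dge_gonad is not None:
        w(result.dge_gonad, "dge_gonad.tsv", index=True)
    w(_frame_groups(result.groups), "homology_groups.tsv")
    w(_frame_clusters(result.clusters1), "clusters_sp1.tsv")
    w(_frame_clusters(result.clusters2), "clusters_sp2.tsv")
    io_tables.write_ortholog_table(result.orthologs, outdir / "orthologs.tsv")
    w(result.bias_pairs, "bias_pairs.tsv")
    io_tables.write_annotation(result.annotation1, outdir / "annotation_sp1.gff3")
    io_tables.write_annotation(result.annotation2, outdir / "annotation_sp2.gff3")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest = {
        "config": {
            k: v for k, v in asdict(config).items()
            if k not in ("sim", "scoring", "ortholog_overrides")
        },
        "scoring": asdict(config.scoring),
        "sim": {
            k: v for k, v in asdict(config.sim).items() if k != "muller"
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
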