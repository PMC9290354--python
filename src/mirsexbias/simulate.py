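"""Synthetic two-species microRNA study generator.

Emulates the comparative design the package analyses: two Drosophila-like
species sharing the six Muller elements (ancestral chromosome arms A-F), with
clustered hairpin loci, conserved one-to-one (and occasionally one-to-many)
families diverged by point mutation, lineage-specific ("novel") loci in the
second species only, optional planted inter-element translocations, and
negative-binomial read counts with sex, batch and library-size structure.

Every draw flows from ``SimulationConfig.seed`` through per-stage
``numpy.random.Generator`` streams, so identical configs give byte-identical
annotations, sequences and count matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .io_tables import CountExperiment, MirnaLocus

__all__ = [
    "MullerMap",
    "SimulationConfig",
    "GroundTruth",
    "simulate_annotation",
    "simulate_sequences",
    "simulate_counts",
    "write_fasta",
]


@dataclass(frozen=True)
class MullerMap:
    """Muller element -> chromosome name per species, with X-linked subsets.

    Defaults follow the melanogaster / pseudoobscura karyotypes: in species 1
    element A is the X; in species 2 the X is a fusion of A (XL) and D (XR),
    D being the neo-X arm.
    """

    elements: tuple[str, ...] = ("A", "B", "C", "D", "E", "F")
    chrom_sp1: dict = field(
        default_factory=lambda: {
            "A": "X", "B": "2L", "C": "2R", "D": "3L", "E": "3R", "F": "4",
        }
    )
    chrom_sp2: dict = field(
        default_factory=lambda: {
            "A": "XL", "B": "4", "C": "3", "D": "XR", "E": "2", "F": "5",
        }
    )
    x_linked_sp1: tuple[str, ...] = ("A",)
    x_linked_sp2: tuple[str, ...] = ("A", "D")
    neo_x: str = "D"

    def chromosome(self, species_index: int, element: str) -> str:
        return (self.chrom_sp1 if species_index == 1 else self.chrom_sp2)[element]

    def x_linked(self, species_index: int) -> tuple[str, ...]:
        return self.x_linked_sp1 if species_index == 1 else self.x_linked_sp2


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    ``n_loci`` counts species-2 loci (the focal species); species 1 carries
    the conserved families only.  ``sex_effect_log2`` is the planted
    log2(male/female) effect given to novel loci on species-2 X-linked
    elements; novel autosomal loci receive half of it, emulating the general
    male bias of young microRNAs with its X-linked amplification.  ``batch_effect_log2`` is the standard deviation of per-locus
    batch coefficients (a batch shift shared by all loci would be absorbed by
    normalization, so batch structure is locus-specific).
    ``conserved_effect_sd`` spreads family-level sex effects shared by both
    species' copies, which is what makes cross-species fold-change
    conservation detectable.  ``frac_duplicated`` tandem-duplicates that
    fraction of conserved families in species 2, producing one-to-many
    homology groups.
    """

    seed: int = 0
    n_loci: int = 150
    n_clusters: int = 30
    muller: MullerMap = field(default_factory=MullerMap)
    frac_novel: float = 0.25
    frac_x: float = 0.3
    sex_effect_log2: float = 1.5
    batch_effect_log2: float = 0.5
    nb_dispersion: float = 0.1
    mean_log_expression: float = 6.0
    mean_log_sd: float = 2.0
    n_replicates_per_sex: int = 2
    translocation_count: int = 0
    substitution_rate: float = 0.05
    cluster_span_bp: int = 5000
    intercluster_gap_bp: int = 50000
    frac_duplicated: float = 0.05
    conserved_effect_sd: float = 0.75
    hairpin_length_range: tuple[int, int] = (60, 150)
    libsize_range: tuple[float, float] = (0.5, 2.0)
    species_names: tuple[str, str] = ("dmel", "dpse")

    def __post_init__(self) -> None:
        for name in ("frac_novel", "frac_x", "frac_duplicated"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.n_replicates_per_sex < 1:
            raise ValueError("need at least one replicate per sex")
        if self.translocation_count < 0:
            raise ValueError("translocation_count must be >= 0")
        if not 0.0 <= self.substitution_rate < 0.5:
            raise ValueError(
                "substitution_rate must be in [0, 0.5); at 0.5 or more the "
                "homology signal is destroyed by design"
            )
        if self.intercluster_gap_bp <= 10000:
            raise ValueError("intercluster_gap_bp must exceed 10000 bp")
        if self.n_clusters < 1 or self.n_loci < 1:
            raise ValueError("need at least one cluster and one locus")
        if self.n_loci < self.n_clusters:
            raise ValueError(
                f"infeasible geometry: {self.n_loci} loci cannot fill "
                f"{self.n_clusters} clusters"
            )

    def rng(self, stage: int, *extra: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage, *extra])


@dataclass
class GroundTruth:
    """Planted truth for every downstream stage.

    ``loci``: one row per simulated locus (both species) with family id, true
    log2 sex effect, age class and Muller element.  ``orthologs``: one row per
    true cross-species pair (one-to-many families give several rows).
    ``clusters``: planted cluster membership per species.  ``translocations``:
    the ortholog pairs planted on discordant Muller elements.
    """

    loci: pd.DataFrame
    orthologs: pd.DataFrame
    clusters: pd.DataFrame
    translocations: pd.DataFrame

    def sex_effects(self, species: str) -> pd.Series:
        sub = self.loci[self.loci["species"] == species]
        return sub.set_index("id")["sex_effect"]


# ---------------------------------------------------------------------------
# annotation


def _draw_cluster_sizes(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    sizes = np.ones(k, dtype=np.int64)
    if n > k:
        sizes += rng.multinomial(n - k, np.full(k, 1.0 / k))
    return sizes


def simulate_annotation(
    config: SimulationConfig,
) -> tuple[list[MirnaLocus], list[MirnaLocus], GroundTruth]:
    """Simulate locus tables for both species plus the planted ground truth.

    Loci are organised in clusters whose within-cluster neighbour gaps stay
    below 10 kb while distinct clusters are separated by more than
    ``intercluster_gap_bp``; conserved families appear on the chromosome of
    the same Muller element in both species except for exactly
    ``translocation_count`` planted translocations.
    """
    rng = config.rng(1)
    mm = config.muller
    sp1, sp2 = config.species_names
    x_elems = set(mm.x_linked(2))
    auto_elems = [e for e in mm.elements if e not in x_elems]

    sizes = _draw_cluster_sizes(rng, config.n_loci, config.n_clusters)
    # element per cluster: frac_x of clusters on species-2 X-linked arms
    cluster_elems = [
        str(rng.choice(sorted(x_elems)))
        if rng.random() < config.frac_x
        else str(rng.choice(auto_elems))
        for _ in range(config.n_clusters)
    ]

    lmin, lmax = config.hairpin_length_range
    fam_counter = 0
    # per-cluster list of member dicts (species-2 view first)
    records: list[dict] = []
    for ci, (size, elem) in enumerate(zip(sizes, cluster_elems)):
        for _ in range(size):
            fam_counter += 1
            fam = f"fam{fam_counter:04d}"
            novel = rng.random() < config.frac_novel
            length = int(rng.integers(lmin, lmax + 1))
            dup = (not novel) and rng.random() < config.frac_duplicated
            records.append(
                {
                    "family": fam,
                    "cluster": ci,
                    "element": elem,
                    "novel": novel,
                    "length": length,
                    "duplicated": dup,
                }
            )

    # plant translocations among one-to-one conserved families
    eligible = [r for r in records if not r["novel"] and not r["duplicated"]]
    if config.translocation_count > len(eligible):
        raise ValueError(
            f"cannot plant {config.translocation_count} translocations among "
            f"{len(eligible)} one-to-one conserved families"
        )
    chosen = rng.choice(len(eligible), size=config.translocation_count, replace=False)
    next_cluster = config.n_clusters
    translocated: list[dict] = []
    for idx in sorted(int(i) for i in chosen):
        rec = eligible[idx]
        others = [e for e in mm.elements if e != rec["element"]]
        rec["element2"] = str(rng.choice(others))
        rec["cluster2"] = next_cluster  # relocated loci form their own cluster
        next_cluster += 1
        translocated.append(rec)
    for rec in records:
        rec.setdefault("element2", rec["element"])
        rec.setdefault("cluster2", rec["cluster"])

    # family-level sex effects: novel loci are male-biased as a class, with
    # the full planted effect on X-linked elements and half on autosomes;
    # conserved families share a random effect across both species' copies
    for rec in records:
        if rec["novel"]:
            rec["effect"] = config.sex_effect_log2 * (
                1.0 if rec["element"] in x_elems else 0.5
            )
        else:
            rec["effect"] = float(rng.normal(0.0, config.conserved_effect_sd))

    def layout(species_index: int) -> list[MirnaLocus]:
        """Place each species' cluster members along its chromosomes."""
        name = sp1 if species_index == 1 else sp2
        members: dict[tuple[str, int], list[dict]] = {}
        for rec in records:
            if species_index == 1 and rec["novel"]:
                continue
            elem = rec["element"] if species_index == 1 else rec["element2"]
            clu = rec["cluster"] if species_index == 1 else rec["cluster2"]
            n_copies = 2 if (species_index == 2 and rec["duplicated"]) else 1
            for k in range(n_copies):  # tandem duplicate sits beside the original
                members.setdefault((elem, clu), []).append((rec, k))
        loci: list[MirnaLocus] = []
        lay_rng = config.rng(1, species_index + 10)
        by_chrom: dict[str, list] = {}
        for (elem, clu), recs in sorted(members.items()):
            chrom = mm.chromosome(species_index, elem)
            by_chrom.setdefault(chrom, []).append((clu, recs))
        for chrom in sorted(by_chrom):
            pos = int(lay_rng.integers(10_000, 100_000))
            for clu, recs in by_chrom[chrom]:
                n_members = len(recs)
                max_gap = min(9000, max(200, config.cluster_span_bp // n_members))
                for j, (rec, copy) in enumerate(recs):
                    if j > 0:
                        pos += int(lay_rng.integers(100, max_gap + 1))
                    start = pos
                    end = start + rec["length"] - 1
                    suffix = "" if copy == 0 else f"-{copy + 1}"
                    elem = rec["element"] if species_index == 1 else rec["element2"]
                    loci.append(
                        MirnaLocus(
                            id=f"{name}-mir-{rec['family'][3:]}{suffix}",
                            species=name,
                            chromosome=chrom,
                            muller=elem,
                            start=start,
                            end=end,
                            strand="+",
                            age_class="novel" if rec["novel"] else "conserved",
                        )
                    )
                    if copy == 0:
                        rec["id_sp%d" % species_index] = loci[-1].id
                    pos = end + 1
                pos += config.intercluster_gap_bp + int(
                    lay_rng.integers(0, config.intercluster_gap_bp)
                )
        return loci

    loci1 = layout(1)
    loci2 = layout(2)

    # ground-truth tables -------------------------------------------------
    id_by_species: dict[str, dict] = {sp1: {}, sp2: {}}
    rows = []
    for loc in loci1 + loci2:
        rows.append(
            {
                "species": loc.species,
                "id": loc.id,
                "muller": loc.muller,
                "age_class": loc.age_class,
            }
        )
    truth_loci = pd.DataFrame(rows)
    fam_of: dict[tuple[str, str], str] = {}
    eff_of: dict[tuple[str, str], float] = {}
    clu_of: dict[tuple[str, str], int] = {}
    for rec in records:
        for sidx, key in ((1, "id_sp1"), (2, "id_sp2")):
            name = sp1 if sidx == 1 else sp2
            if key not in rec:
                continue
            base_id = rec[key]
            ids = [base_id]
            if sidx == 2 and rec["duplicated"]:
                ids = [f"{name}-mir-{rec['family'][3:]}", f"{name}-mir-{rec['family'][3:]}-2"]
            for i in ids:
                fam_of[(name, i)] = rec["family"]
                eff_of[(name, i)] = rec["effect"]
                clu_of[(name, i)] = rec["cluster"] if sidx == 1 else rec["cluster2"]
    truth_loci["family"] = [
        fam_of[(r.species, r.id)] for r in truth_loci.itertuples()
    ]
    truth_loci["sex_effect"] = [
        eff_of[(r.species, r.id)] for r in truth_loci.itertuples()
    ]
    clusters = pd.DataFrame(
        {
            "species": truth_loci["species"],
            "id": truth_loci["id"],
            "cluster": [clu_of[(r.species, r.id)] for r in truth_loci.itertuples()],
        }
    )

    ortho_rows = []
    trans_rows = []
    for rec in records:
        if "id_sp1" not in rec:
            continue
        sp2_ids = [rec["id_sp2"]]
        if rec["duplicated"]:
            sp2_ids.append(rec["id_sp2"] + "-2")
        for i2 in sp2_ids:
            ortho_rows.append(
                {
                    "id1": rec["id_sp1"],
                    "id2": i2,
                    "muller1": rec["element"],
                    "muller2": rec["element2"],
                }
            )
        if rec["element"] != rec["element2"]:
            trans_rows.append(
                {
                    "id1": rec["id_sp1"],
                    "id2": rec["id_sp2"],
                    "muller1": rec["element"],
                    "muller2": rec["element2"],
                }
            )
    orthologs = pd.DataFrame(ortho_rows, columns=["id1", "id2", "muller1", "muller2"])
    translocations = pd.DataFrame(
        trans_rows, columns=["id1", "id2", "muller1", "muller2"]
    )

    truth = GroundTruth(
        loci=truth_loci,
        orthologs=orthologs,
        clusters=clusters,
        translocations=translocations,
    )
    return loci1, loci2, truth


# ---------------------------------------------------------------------------
# sequences


_BASES = np.array(list("ACGT"))


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Point-mutate each site independently with the given per-site rate."""
    out = seq.copy()
    hits = np.nonzero(rng.random(seq.size) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[int(rng.integers(0, 3))]
    return out


def simulate_sequences(
    loci1: list[MirnaLocus],
    loci2: list[MirnaLocus],
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[dict[str, str], dict[str, str]]:
    """Simulate hairpin sequences: ortholog copies descend from a common
    ancestor mutated at ``substitution_rate`` per site per lineage; unpaired
    (novel) loci are independent random sequence at GC ~ 0.5."""
    rng = config.rng(2)
    fam_ancestor: dict[str, np.ndarray] = {}
    fam_lookup = truth.loci.set_index(["species", "id"])["family"]
    seqs1: dict[str, str] = {}
    seqs2: dict[str, str] = {}
    length_of: dict[str, int] = {}
    for loc in loci1 + loci2:
        fam = fam_lookup[(loc.species, loc.id)]
        length_of.setdefault(fam, loc.length)

    paired_fams = set(
        fam_lookup[(loci1[0].species if loci1 else config.species_names[0], i)]
        for i in truth.orthologs["id1"]
    ) if len(truth.orthologs) else set()

    # ancestors drawn in deterministic family order
    for fam in sorted(length_of):
        fam_ancestor[fam] = _BASES[rng.integers(0, 4, size=length_of[fam])]

    for loc in sorted(loci1, key=lambda l: l.id):
        fam = fam_lookup[(loc.species, loc.id)]
        seqs1[loc.id] = "".join(
            _mutate(fam_ancestor[fam], config.substitution_rate, rng)
        )
    for loc in sorted(loci2, key=lambda l: l.id):
        fam = fam_lookup[(loc.species, loc.id)]
        if fam in paired_fams:
            seqs2[loc.id] = "".join(
                _mutate(fam_ancestor[fam], config.substitution_rate, rng)
            )
        else:
            # unpaired locus: fresh random sequence, unrelated to any ancestor
            seqs2[loc.id] = "".join(_BASES[rng.integers(0, 4, size=loc.length)])
    return seqs1, seqs2


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n{seqs[name]}\n")


# ---------------------------------------------------------------------------
# counts


def simulate_counts(
    loci: list[MirnaLocus],
    truth: GroundTruth,
    config: SimulationConfig,
    design: Literal["paired", "unpaired"] = "paired",
    mode: Literal["whole", "gonad"] = "whole",
) -> CountExperiment:
    """Draw an NB count matrix for one species' loci.

    log2 mean = per-locus base + per-locus batch coefficient + sex effect
    (males; in gonad mode the testis samples), then scaled by a per-sample
    library-size factor drawn log-uniformly from ``libsize_range``.  Variance
    follows var = mu + mu^2 * nb_dispersion; dispersions below 1e-6 switch to
    the Poisson limit.
    """
    if not loci:
        raise ValueError("no loci to simulate counts for")
    species = loci[0].species
    sp_index = 1 if species == config.species_names[0] else 2
    rng = config.rng(3, sp_index, 0 if mode == "whole" else 1)
    ids = [loc.id for loc in loci]
    effects = truth.sex_effects(species).reindex(ids).fillna(0.0).to_numpy()

    n_rep = config.n_replicates_per_sex
    sample_ids: list[str] = []
    sex: list[str] = []
    tissue: list[str] = []
    batch: list[str] = []
    for r in range(1, n_rep + 1):
        for s in ("male", "female"):
            tag = "t" if (mode == "gonad" and s == "male") else (
                "o" if mode == "gonad" else s[0]
            )
            sample_ids.append(f"{species}_{tag}{r}")
            sex.append(s)
            tissue.append(
                "whole" if mode == "whole" else ("testis" if s == "male" else "ovary")
            )
            batch.append(f"b{r}" if design == "paired" else f"b{r}{s[0]}")

    n_loci = len(ids)
    n_samples = len(sample_ids)
    base = rng.normal(config.mean_log_expression, config.mean_log_sd, size=n_loci)
    batches = sorted(set(batch))
    batch_coef = {
        b: (np.zeros(n_loci) if i == 0
            else rng.normal(0.0, config.batch_effect_log2, size=n_loci))
        for i, b in enumerate(batches)
    }
    lo, hi = config.libsize_range
    libsize = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))

    male = np.array([1.0 if s == "male" else 0.0 for s in sex])
    log2mu = (
        base[:, None]
        + np.stack([batch_coef[b] for b in batch], axis=1)
        + effects[:, None] * male[None, :]
    )
    mu = np.exp2(log2mu) * libsize[None, :]
    if config.nb_dispersion < 1e-6:
        counts = rng.poisson(mu)
    else:
        r_nb = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(r_nb, r_nb / (r_nb + mu))
    frame = pd.DataFrame(counts.astype(np.int64), index=ids, columns=sample_ids)
    meta = pd.DataFrame(
        {"sex": sex, "tissue": tissue, "batch": batch},
        index=pd.Index(sample_ids, name="sample"),
    )
    return CountExperiment(frame, meta)
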