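"""Readers and writers for the annotation, count, ortholog and tree formats.

Coordinates are 1-based and inclusive throughout (NCBI convention); any
half-open arithmetic is internal to the functions that need it.  TSV files are
tab-separated with ``.`` decimals, no quoting, and ``#``-prefixed comment
lines.  All readers validate invariants and raise rather than silently coerce.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MULLER_ELEMENTS = ("A", "B", "C", "D", "E", "F")
AGE_CLASSES = ("conserved", "novel")

__all__ = [
    "MirnaLocus",
    "CountExperiment",
    "MULLER_ELEMENTS",
    "AGE_CLASSES",
    "read_annotation",
    "write_annotation",
    "loci_to_frame",
    "read_counts",
    "write_counts",
    "read_ortholog_table",
    "write_ortholog_table",
    "write_newick",
    "write_report",
]


@dataclass(frozen=True)
class MirnaLocus:
    """One annotated microRNA hairpin locus.

    ``muller`` is one of the six ancestral Drosophila chromosome arms A-F, or
    ``"unknown"`` when the arm assignment is missing.  ``age_class`` separates
    deeply conserved microRNAs from lineage-specific ("novel") ones.
    ``multimapper_flag`` marks loci mapping with 100% identity to multiple
    genomic regions; such loci are excluded from expression analyses.
    """

    id: str
    species: str
    chromosome: str
    muller: str
    start: int
    end: int
    strand: str = "+"
    age_class: str = "conserved"
    multimapper_flag: bool = False

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"locus {self.id}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"locus {self.id}: end ({self.end}) < start ({self.start})"
            )
        if self.muller not in MULLER_ELEMENTS and self.muller != "unknown":
            raise ValueError(f"locus {self.id}: bad Muller element {self.muller!r}")
        if self.strand not in ("+", "-", "unknown"):
            raise ValueError(f"locus {self.id}: bad strand {self.strand!r}")
        if self.age_class not in AGE_CLASSES:
            raise ValueError(f"locus {self.id}: bad age_class {self.age_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class CountExperiment:
    """Integer read-count matrix (loci x samples) plus per-sample metadata.

    ``samples`` is indexed by sample id with columns ``sex`` (male/female),
    ``tissue`` (whole/testis/ovary) and ``batch``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            missing = set(self.counts.columns) ^ set(self.samples.index)
            raise ValueError(
                "count matrix columns and sample metadata disagree: "
                + ", ".join(sorted(map(str, missing)))
            )
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(vals == np.floor(vals)):
                raise ValueError("count matrix contains non-integer entries")
            self.counts = self.counts.astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("count matrix contains negative entries")
        for col in ("sex", "batch"):
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata lacks required column {col!r}")
            if self.samples[col].isna().any():
                bad = self.samples.index[self.samples[col].isna()].tolist()
                raise ValueError(f"samples missing {col}: {bad}")
        if "tissue" not in self.samples.columns:
            self.samples = self.samples.assign(tissue="whole")

    @property
    def locus_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    def subset_loci(self, ids: Sequence[str]) -> "CountExperiment":
        return CountExperiment(self.counts.loc[list(ids)], self.samples.copy())


# ---------------------------------------------------------------------------
# annotation


_GFF_COLS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def _locus_from_gff_fields(fields: list[str], lineno: int) -> MirnaLocus:
    attrs = {}
    for item in fields[8].rstrip(";").split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        attrs[key.strip()] = value.strip()
    if "ID" not in attrs:
        raise ValueError(f"line {lineno}: GFF3 record lacks an ID attribute")
    try:
        start, end = int(fields[3]), int(fields[4])
    except ValueError as exc:
        raise ValueError(f"line {lineno}: malformed coordinates") from exc
    muller = attrs.get("muller", "unknown")
    if muller not in MULLER_ELEMENTS and muller != "unknown":
        warnings.warn(
            f"line {lineno}: unknown Muller label {muller!r}, recording as unknown"
        )
        muller = "unknown"
    try:
        return MirnaLocus(
            id=attrs["ID"],
            species=attrs.get("species", "unknown"),
            chromosome=fields[0],
            muller=muller,
            start=start,
            end=end,
            strand=fields[6] if fields[6] in "+-" else "unknown",
            age_class=attrs.get("age_class", "conserved"),
            multimapper_flag=attrs.get("multimapper", "0") in ("1", "true", "True"),
        )
    except ValueError as exc:
        raise ValueError(f"line {lineno}: {exc}") from exc


def read_annotation(path, dialect: str = "gff3") -> list[MirnaLocus]:
    """Read a microRNA locus annotation as GFF3 or TSV.

    Malformed coordinates raise with the offending line number; unknown Muller
    labels are kept as ``"unknown"`` with a warning.  An empty file yields an
    empty list (with a warning).
    """
    if dialect not in ("gff3", "tsv"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    loci: list[MirnaLocus] = []
    if dialect == "gff3":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 9:
                    raise ValueError(
                        f"line {lineno}: expected 9 GFF3 columns, got {len(fields)}"
                    )
                loci.append(_locus_from_gff_fields(fields, lineno))
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
        if len(df) == 0:
            warnings.warn(f"{path}: empty annotation")
            return []
        for i, row in df.iterrows():
            muller = str(row.get("muller", "unknown"))
            if muller not in MULLER_ELEMENTS and muller != "unknown":
                warnings.warn(f"row {i}: unknown Muller label {muller!r}")
                muller = "unknown"
            try:
                loci.append(
                    MirnaLocus(
                        id=str(row["id"]),
                        species=str(row.get("species", "unknown")),
                        chromosome=str(row["chromosome"]),
                        muller=muller,
                        start=int(row["start"]),
                        end=int(row["end"]),
                        strand=str(row.get("strand", "unknown")),
                        age_class=str(row.get("age_class", "conserved")),
                        multimapper_flag=bool(row.get("multimapper_flag", False)),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"row {i}: {exc}") from exc
    if not loci:
        warnings.warn(f"{path}: empty annotation")
    seen: dict[tuple[str, str], int] = {}
    for loc in loci:
        key = (loc.species, loc.id)
        if key in seen:
            raise ValueError(f"duplicate locus id {loc.id!r} for species {loc.species}")
        seen[key] = 1
    return loci


def write_annotation(loci: Iterable[MirnaLocus], path, dialect: str = "gff3") -> None:
    loci = list(loci)
    if dialect == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for loc in loci:
                attrs = (
                    f"ID={loc.id};species={loc.species};muller={loc.muller};"
                    f"age_class={loc.age_class};multimapper={int(loc.multimapper_flag)}"
                )
                fh.write(
                    "\t".join(
                        [
                            loc.chromosome,
                            "mirsexbias",
                            "pre_miRNA",
                            str(loc.start),
                            str(loc.end),
                            ".",
                            loc.strand if loc.strand in "+-" else ".",
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )
    elif dialect == "tsv":
        loci_to_frame(loci).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")


def loci_to_frame(loci: Iterable[MirnaLocus]) -> pd.DataFrame:
    rows = [
        {
            "id": loc.id,
            "species": loc.species,
            "chromosome": loc.chromosome,
            "muller": loc.muller,
            "start": loc.start,
            "end": loc.end,
            "strand": loc.strand,
            "age_class": loc.age_class,
            "multimapper_flag": loc.multimapper_flag,
        }
        for loc in loci
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "id", "species", "chromosome", "muller", "start", "end", "strand",
            "age_class", "multimapper_flag",
        ],
    )


# ---------------------------------------------------------------------------
# counts


def read_counts(counts_path, metadata_path) -> CountExperiment:
    """Read a loci x samples count TSV together with its sample metadata TSV."""
    counts = pd.read_csv(counts_path, sep="\t", comment="#", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", comment="#", index_col=0)
    meta.index = meta.index.astype(str)
    counts.columns = counts.columns.astype(str)
    missing = [s for s in counts.columns if s not in meta.index]
    extra = [s for s in meta.index if s not in counts.columns]
    if missing or extra:
        raise ValueError(
            "sample id mismatch between counts and metadata: "
            f"counts-only={missing}, metadata-only={extra}"
        )
    meta = meta.loc[list(counts.columns)]
    return CountExperiment(counts, meta)


def write_counts(experiment: CountExperiment, counts_path, metadata_path) -> None:
    experiment.counts.to_csv(counts_path, sep="\t", index_label="locus")
    experiment.samples.to_csv(metadata_path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# ortholog tables


_ORTHO_COLS = [
    "id1", "id2", "muller1", "muller2",
    "chromosome1", "start1", "end1", "chromosome2", "start2", "end2",
]


def read_ortholog_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("id1", "id2", "muller1", "muller2"):
        if col not in df.columns:
            raise ValueError(f"ortholog table lacks required column {col!r}")
    if df.duplicated(subset=["id1", "id2"]).any():
        dupes = df[df.duplicated(subset=["id1", "id2"])][["id1", "id2"]]
        raise ValueError(f"duplicated ortholog pairs: {dupes.to_records(index=False)}")
    return df


def write_ortholog_table(df: pd.DataFrame, path) -> None:
    cols = [c for c in _ORTHO_COLS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df.to_csv(path, sep="\t", index=False, columns=cols)


# ---------------------------------------------------------------------------
# trees


def write_newick(tree) -> str:
    """Serialize a tree (``mirsexbias.homology.TreeNode``) as canonical newick.

    Children are ordered by their smallest leaf label so the output is
    deterministic and diffable.  Branch lengths are written at full precision
    (``repr`` round-trip).
    """

    def fmt_len(x) -> str:
        if x is None:
            return ""
        return f":{np.format_float_positional(float(x), trim='-')}"

    seen: set[int] = set()

    def min_leaf(node, stack=()) -> str:
        if id(node) in stack:
            raise ValueError("cyclic tree structure")
        if not node.children:
            return node.name or ""
        stack = stack + (id(node),)
        return min(min_leaf(c, stack) for c in node.children)

    def render(node) -> str:
        if id(node) in seen:
            raise ValueError("cyclic tree structure")
        seen.add(id(node))
        if not node.children:
            return f"{node.name}{fmt_len(node.length)}"
        parts = sorted(node.children, key=min_leaf)
        inner = ",".join(render(c) for c in parts)
        name = node.name or ""
        return f"({inner}){name}{fmt_len(node.length)}"

    if not tree.children and tree.name:
        return f"{tree.name};"
    return render(tree) + ";"


def write_report(frame: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    """Write any result table as a plain TSV (deterministic float formatting)."""
    frame.to_csv(path, sep="\t", index=False, float_format=float_format)
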