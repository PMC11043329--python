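"""Gene annotation, a-priori gene groups, and the TSS-anchored promoter frame.

Promoters are defined as -3 kb to +1 kb around the transcription start
site (TSS), always 4000 bp.  All genomic intervals are 0-based half-open
(bedgraph convention).  In the promoter frame, offset 0 is the TSS base
itself (first base of the downstream side) and offsets run -3000..+999.
For minus-strand genes the frame mirrors around the TSS so that
"upstream"/"downstream" are transcriptional, not genomic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

WINDOW_UPSTREAM = 3000
WINDOW_DOWNSTREAM = 1000
WINDOW_LENGTH = WINDOW_UPSTREAM + WINDOW_DOWNSTREAM

GROUP_LABELS = ("skeletal", "common", "heart", "nonmuscle")

#: Packaged gene-group configuration: four a-priori groups of mouse genes,
#: stratified by expression pattern.  The skeletal group holds genes
#: expressed solely in skeletal muscle; "common" in both skeletal and
#: cardiac muscle; "heart" solely in cardiac muscle; "nonmuscle" covers
#: fibroblast-, endothelial- and neuron-specific genes (26 unique genes;
#: the protein alias Cd31 duplicates Pecam1 and is represented once).
DEFAULT_GROUPS: dict[str, tuple[str, ...]] = {
    "skeletal": (
        "Neb", "Scn4a", "Cacna1s", "Tnni1", "Tnni2", "Myh1",
        "Myh2", "Myh3", "Myh4", "Myogenin", "Myod1", "Ryr1",
    ),
    "common": (
        "Actn2", "Kcnj2", "Mef2C", "Myh6", "Myl2", "Sln", "Ttn",
        "Myoglobin", "Myh7",
    ),
    "heart": ("Cacna1c", "Kcna4", "Nebl", "Ryr2", "Scn5a", "Tnni3"),
    "nonmuscle": (
        # fibroblast-specific
        "Col1a2", "S100a4", "Thy1", "Tcf21", "Atl1", "Col1a1", "Postn",
        # endothelial-specific (Pecam1 == Cd31)
        "Cdh1", "Eng", "Flt1", "Flt4", "Pecam1", "Tek", "Vcam1",
        "Vegfa", "Vwf",
        # neuron-specific
        "Dcx", "Eno2", "L1cam", "Map2", "Mapt", "Ncam1", "Neurod1",
        "Nlgn1", "Rbfox3", "Syn1",
    ),
}


class AnnotationError(ValueError):
    """Raised for malformed annotation or group-configuration input."""


@dataclass(frozen=True)
class GeneRecord:
    """A gene with a single TSS and its group membership.

    ``tss`` is the 0-based genomic position of the first transcribed base.
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str
    group: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.tss < 0:
            raise AnnotationError(
                f"gene {self.gene_id!r}: negative TSS coordinate {self.tss}"
            )
        if self.group not in GROUP_LABELS:
            raise AnnotationError(
                f"gene {self.gene_id!r}: unknown group {self.group!r}; "
                f"expected one of {GROUP_LABELS}"
            )


@dataclass(frozen=True)
class PromoterWindow:
    """Strand-aware genomic interval of exactly 4000 bp around a TSS."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end - self.start != WINDOW_LENGTH:
            raise AnnotationError(
                f"promoter window for {self.gene_id!r} has length "
                f"{self.end - self.start}, expected {WINDOW_LENGTH}"
            )
        if self.start < 0:
            raise AnnotationError(
                f"promoter window for {self.gene_id!r} extends below coordinate 0 "
                f"(start={self.start}); pad synthetic chromosomes"
            )


def window_offsets() -> np.ndarray:
    """Promoter-frame offsets -3000..+999 (ascending, length 4000)."""
    return np.arange(-WINDOW_UPSTREAM, WINDOW_DOWNSTREAM)


def default_group_config() -> dict[str, list[str]]:
    """A fresh copy of the packaged four-group gene configuration."""
    return {label: list(genes) for label, genes in DEFAULT_GROUPS.items()}


def validate_group_config(groups: Mapping[str, Sequence[str]]) -> dict[str, list[str]]:
    """Check disjointness and non-emptiness of a group mapping."""
    seen: dict[str, str] = {}
    out: dict[str, list[str]] = {}
    for label, genes in groups.items():
        genes = list(genes)
        if not genes:
            raise AnnotationError(f"group {label!r} is empty")
        for g in genes:
            if g in seen:
                raise AnnotationError(
                    f"gene {g!r} appears in both {seen[g]!r} and {label!r}; "
                    "groups must be disjoint"
                )
            seen[g] = label
        out[label] = genes
    if not out:
        raise AnnotationError("group configuration is empty")
    return out


def load_group_config(path: str | Path) -> dict[str, list[str]]:
    """Load a YAML group configuration (mapping group label -> gene list)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise AnnotationError(f"{path}: expected a mapping of group -> gene list")
    return validate_group_config(raw)


def write_group_config(groups: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({k: list(v) for k, v in groups.items()}, fh, sort_keys=False)


def load_annotation(path: str | Path) -> list[GeneRecord]:
    """Load a TSV gene annotation with columns gene_id/chrom/tss/strand/group.

    Raises :class:`AnnotationError` naming the offending row for malformed
    strands, negative coordinates, unknown group labels, or duplicate ids.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    required = ["gene_id", "chrom", "tss", "strand", "group"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise AnnotationError(f"{path}: missing column(s) {missing}")
    records: list[GeneRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            tss = int(row.tss)
        except (TypeError, ValueError):
            raise AnnotationError(
                f"{path} row {i}: non-integer tss {row.tss!r}"
            ) from None
        try:
            rec = GeneRecord(str(row.gene_id), str(row.chrom), tss,
                             str(row.strand), str(row.group))
        except AnnotationError as exc:
            raise AnnotationError(f"{path} row {i}: {exc}") from None
        if rec.gene_id in seen:
            raise AnnotationError(f"{path} row {i}: duplicate gene_id {rec.gene_id!r}")
        seen.add(rec.gene_id)
        records.append(rec)
    return records


def write_annotation(records: Iterable[GeneRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.gene_id, r.chrom, r.tss, r.strand, r.group) for r in records],
        columns=["gene_id", "chrom", "tss", "strand", "group"],
    ).to_csv(path, sep="\t", index=False)


def promoter_window(g: GeneRecord) -> PromoterWindow:
    """The -3 kb..+1 kb (transcriptional) promoter interval of a gene.

    Plus strand: [tss-3000, tss+1000).  Minus strand, mirrored so the
    transcriptional upstream side is genomic-rightward: [tss-999, tss+3001).
    """
    if g.strand == "+":
        start = g.tss - WINDOW_UPSTREAM
        end = g.tss + WINDOW_DOWNSTREAM
    else:
        start = g.tss - (WINDOW_DOWNSTREAM - 1)
        end = g.tss + WINDOW_UPSTREAM + 1
    return PromoterWindow(g.gene_id, g.chrom, start, end, g.strand)


def to_relative_frame(values: np.ndarray, strand: str) -> np.ndarray:
    """Map a per-base genomic signal over a promoter window into offset space.

    ``values`` must cover the full window in ascending genomic order
    (length 4000).  Output index j holds the value at transcriptional
    offset j-3000: for plus-strand genes offset p maps to genomic tss+p,
    for minus-strand genes to tss-p (a reversal of the window vector).
    """
    arr = np.asarray(values)
    if arr.shape[-1] != WINDOW_LENGTH:
        raise AnnotationError(
            f"signal covers {arr.shape[-1]} bases, expected {WINDOW_LENGTH}"
        )
    if strand == "+":
        return arr.copy()
    if strand == "-":
        return arr[..., ::-1].copy()
    raise AnnotationError(f"strand must be '+' or '-', got {strand!r}")


def windows_to_bed6(windows: Iterable[PromoterWindow], path: str | Path) -> None:
    """Export promoter windows as BED6 (name=gene_id, score=0)."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.gene_id}\t0\t{w.strand}\n")
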