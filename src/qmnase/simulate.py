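"""Synthetic MNase-seq / ChIP-seq data with known ground truth.

The generator emulates the statistical structure of a two-state
promoter nucleosome experiment: per-gene nucleosome arrays with
~190-bp spacing across the 4-kb promoter window, fragment lengths drawn
from a mono/di-nucleosome mixture (a light MNase digest leaves >95%
mononucleosomes), planted repositioning perturbations (shift, loss,
build-up) in chosen groups, and ChIP enrichment boxes over an
input-like background.  Crucially the per-gene architecture is shared
between conditions — the same promoter is measured twice — which is what
gives the paired per-bp t-test its power.

Every function takes an explicit ``numpy.random.Generator``; identical
seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from qmnase.annotation import (
    GeneRecord,
    WINDOW_LENGTH,
    default_group_config,
    promoter_window,
    to_relative_frame,
)
from qmnase.coverage import FRAGMENT_COLUMNS, center_coverage, size_filter
from qmnase.dynamics import OFFSET_MIN, CoverageProfile, normalize_profile


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class Perturbation:
    """A planted nucleosome change in one gene group.

    kind 'shift': centers inside [start, end] move ``magnitude`` bp
    downstream (negative = upstream).  kind 'loss'/'buildup': sampling
    weight of centers inside the region is multiplied by ``magnitude``
    (<1 depletes, >1 enriches).  Offsets are promoter-relative,
    inclusive.
    """

    kind: str
    start: int
    end: int
    magnitude: float
    group: str

    def __post_init__(self) -> None:
        if self.kind not in ("shift", "loss", "buildup"):
            raise SimulationError(f"unknown perturbation kind {self.kind!r}")
        if self.kind == "loss" and not 0 <= self.magnitude < 1:
            raise SimulationError("loss factor must be in [0, 1)")
        if self.kind == "buildup" and self.magnitude <= 1:
            raise SimulationError("buildup factor must be > 1")


@dataclass(frozen=True)
class EnrichmentBox:
    """A planted ChIP enrichment: fold-increase of IP sampling density
    over [start, end] for one group in one condition."""

    start: int
    end: int
    fold: float
    group: str
    condition: str


@dataclass
class SyntheticSpec:
    """Generator parameters; defaults model a myoblast/myotube
    differentiation experiment.

    Group sizes are the four a-priori groups (12/9/6/26 genes);
    nucleosome spacing ~190 bp with positional jitter; fragment lengths
    a 95:5 mono/di-nucleosome Gaussian mixture (mono N(165, 10^2),
    di N(330, 20^2)); occupancy per nucleosome is bell-shaped with
    30-bp SD on the fragment-centre positions.
    """

    n_genes: dict[str, int] = field(default_factory=lambda: {
        "skeletal": 12, "common": 9, "heart": 6, "nonmuscle": 26})
    spacing_mean: float = 190.0
    spacing_jitter_sd: float = 15.0
    peak_width_sd: float = 30.0
    mono_length_mean: float = 165.0
    mono_length_sd: float = 10.0
    di_length_mean: float = 330.0
    di_length_sd: float = 20.0
    mono_fraction: float = 0.95
    anchor_jitter_sd: float = 10.0
    depth: int = 5000
    chip_depth: int = 5000
    perturbations: tuple[Perturbation, ...] = ()
    chip_boxes: tuple[EnrichmentBox, ...] = ()
    tss: int = 6000
    chrom_length: int = 12000

    def __post_init__(self) -> None:
        for name in ("spacing_jitter_sd", "peak_width_sd", "mono_length_sd",
                     "di_length_sd"):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be > 0")
        if not 0.0 <= self.mono_fraction <= 1.0:
            raise SimulationError("mono_fraction must be in [0, 1]")


def default_perturbations() -> tuple[Perturbation, ...]:
    """Planted skeletal-group changes emulating the five differential
    region archetypes: three downstream shifts, one build-up, one loss."""
    return (
        Perturbation("shift", -2500, -2400, 120.0, "skeletal"),
        Perturbation("buildup", -2150, -1950, 3.0, "skeletal"),
        Perturbation("shift", -650, -400, 120.0, "skeletal"),
        Perturbation("loss", -50, 100, 0.15, "skeletal"),
        Perturbation("shift", 600, 700, 120.0, "skeletal"),
    )


def default_chip_boxes() -> tuple[EnrichmentBox, ...]:
    """Planted Sp3-like binding: myotube sites on muscle genes and
    control-cell sites on non-muscle genes, concentrated 2-3 kb upstream
    of the TSS."""
    return (
        EnrichmentBox(-2800, -2600, 8.0, "skeletal", "myotube"),
        EnrichmentBox(-2800, -2600, 8.0, "common", "myotube"),
        EnrichmentBox(-2650, -2450, 8.0, "nonmuscle", "control"),
    )


def demo_spec() -> SyntheticSpec:
    """The packaged demonstration spec: default architecture with the
    five skeletal perturbations and the ChIP enrichment boxes planted."""
    return SyntheticSpec(perturbations=default_perturbations(),
                         chip_boxes=default_chip_boxes())


# ---------------------------------------------------------------------------
# annotation

def synthetic_annotation(spec: SyntheticSpec) -> tuple[list[GeneRecord], dict[str, list[str]]]:
    """One padded chromosome per gene; strands alternate so both frame
    orientations are exercised.  Gene names reuse the packaged group
    lists where sizes allow, with synthetic names for any extras."""
    defaults = default_group_config()
    records: list[GeneRecord] = []
    groups: dict[str, list[str]] = {}
    i = 0
    for label, n in spec.n_genes.items():
        names = list(defaults.get(label, []))[:n]
        names += [f"{label}_{j:02d}" for j in range(len(names), n)]
        groups[label] = names
        for name in names:
            strand = "+" if i % 2 == 0 else "-"
            records.append(GeneRecord(name, f"chr_{name}", spec.tss, strand, label))
            i += 1
    return records, groups


def chrom_sizes(spec: SyntheticSpec,
                records: Sequence[GeneRecord]) -> dict[str, int]:
    return {r.chrom: spec.chrom_length for r in records}


# ---------------------------------------------------------------------------
# architecture and fragments

def gene_architecture(spec: SyntheticSpec, rng: np.random.Generator,
                      group: str | None = None) -> np.ndarray:
    """Nucleosome centre offsets for one promoter: a jittered array at
    ``spacing_mean`` covering the window plus a margin.

    When ``group`` is given, the nucleosome nearest the midpoint of
    each of the group's perturbation windows is re-positioned onto that
    midpoint (with ``anchor_jitter_sd`` bp of cross-gene jitter).  This
    models the positioned nucleosomes that regulated promoters share
    across co-regulated genes - the alignment that makes per-bp group
    statistics coherent in the first place.  The anchoring is part of
    the shared (pre-differentiation) architecture, so both conditions
    carry it and only the condition-specific perturbation differs.
    """
    margin = 150.0
    centers = []
    c = OFFSET_MIN - margin + rng.uniform(0, spec.spacing_mean)
    limit = OFFSET_MIN + WINDOW_LENGTH + margin
    while c < limit:
        centers.append(c)
        c += spec.spacing_mean + rng.normal(0, spec.spacing_jitter_sd)
    arr = np.asarray(centers)
    if group is not None:
        for p in spec.perturbations:
            if p.group != group or arr.size == 0:
                continue
            mid = (p.start + p.end) / 2.0
            arr[int(np.argmin(np.abs(arr - mid)))] = (
                mid + rng.normal(0, spec.anchor_jitter_sd))
        arr = np.sort(arr)
    return arr


def _perturbed(centers: np.ndarray, perturbations: Sequence[Perturbation],
               group: str) -> tuple[np.ndarray, np.ndarray]:
    centers = centers.copy()
    weights = np.ones_like(centers)
    for p in perturbations:
        if p.group != group:
            continue
        inside = (centers >= p.start) & (centers <= p.end)
        if p.kind == "shift":
            centers[inside] += p.magnitude
        else:
            weights[inside] *= p.magnitude
    return centers, weights


def _fragment_lengths(spec: SyntheticSpec, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    mono = rng.random(n) < spec.mono_fraction
    lengths = np.where(
        mono,
        rng.normal(spec.mono_length_mean, spec.mono_length_sd, n),
        rng.normal(spec.di_length_mean, spec.di_length_sd, n),
    )
    return np.maximum(np.rint(lengths).astype(np.int64), 10)


def _sample_positions(centers: np.ndarray, weights: np.ndarray, n: int,
                      spec: SyntheticSpec, rng: np.random.Generator
                      ) -> np.ndarray:
    if centers.size == 0 or weights.sum() == 0:
        raise SimulationError("no nucleosome centers to sample from")
    prob = weights / weights.sum()
    idx = rng.choice(centers.size, size=n, p=prob)
    return centers[idx] + rng.normal(0, spec.peak_width_sd, n)


def _positions_to_fragments(positions: np.ndarray, lengths: np.ndarray,
                            gene: GeneRecord, spec: SyntheticSpec
                            ) -> pd.DataFrame:
    """Offsets -> genomic fragments whose centre base lands on the
    sampled position (centre convention c = start + L//2)."""
    if gene.strand == "+":
        gcenter = gene.tss + np.rint(positions).astype(np.int64)
    else:
        gcenter = gene.tss - np.rint(positions).astype(np.int64)
    start = gcenter - lengths // 2
    end = start + lengths
    keep = (start >= 0) & (end <= spec.chrom_length)
    return pd.DataFrame({"chrom": gene.chrom, "start": start[keep],
                         "end": end[keep]})


def simulate_promoter_fragments(spec: SyntheticSpec, gene: GeneRecord,
                                condition: str, rng: np.random.Generator,
                                centers: np.ndarray | None = None
                                ) -> tuple[pd.DataFrame, dict]:
    """MNase fragments for one promoter in one condition.

    ``centers`` lets callers share one architecture between conditions
    (the paired design); when omitted a fresh architecture is drawn.
    Perturbations apply only to the 'myotube' condition of the gene's
    group.  Returns the fragment table and a ground-truth record.
    """
    if centers is None:
        centers = gene_architecture(spec, rng, group=gene.group)
    if condition == "myotube":
        eff_centers, weights = _perturbed(centers, spec.perturbations, gene.group)
    else:
        eff_centers, weights = centers.copy(), np.ones_like(centers)
    truth = {
        "gene_id": gene.gene_id,
        "condition": condition,
        "centers": eff_centers,
        "perturbations": [p for p in spec.perturbations if p.group == gene.group],
    }
    if spec.depth == 0:
        return pd.DataFrame(columns=FRAGMENT_COLUMNS), truth
    positions = _sample_positions(eff_centers, weights, spec.depth, spec, rng)
    lengths = _fragment_lengths(spec, spec.depth, rng)
    return _positions_to_fragments(positions, lengths, gene, spec), truth


def fragments_to_profile(frags: pd.DataFrame, gene: GeneRecord,
                         condition: str, spec: SyntheticSpec,
                         min_len: int = 130, max_len: int = 200
                         ) -> CoverageProfile:
    """Fragments -> size filter -> centre coverage -> strand-corrected
    normalized promoter profile (the standard per-gene pipeline)."""
    kept = size_filter(frags, min_len, max_len)
    track = center_coverage(kept, chrom_sizes={gene.chrom: spec.chrom_length})
    w = promoter_window(gene)
    dense = track.dense(gene.chrom, w.start, w.end)
    values = to_relative_frame(dense, gene.strand)
    return normalize_profile(CoverageProfile(gene.gene_id, condition, values))


def simulate_group_profiles(spec: SyntheticSpec, group: str, n_genes: int,
                            rng: np.random.Generator
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Paired (control, myotube) normalized profile matrices for a group,
    built through the full fragment pipeline."""
    ctrl_rows, myo_rows = [], []
    for j in range(n_genes):
        gene = GeneRecord(f"{group}_{j:02d}", f"chr_{group}_{j:02d}",
                          spec.tss, "+" if j % 2 == 0 else "-", group)
        centers = gene_architecture(spec, rng, group=group)
        for cond, rows in (("control", ctrl_rows), ("myotube", myo_rows)):
            frags, _ = simulate_promoter_fragments(spec, gene, cond, rng,
                                                   centers=centers)
            rows.append(fragments_to_profile(frags, gene, cond, spec).values)
    return np.vstack(ctrl_rows), np.vstack(myo_rows)


# ---------------------------------------------------------------------------
# null generator (t-test calibration)

def occupancy_curve(spec: SyntheticSpec, rng: np.random.Generator,
                    baseline: float = 0.3, bump_sd: float = 40.0) -> np.ndarray:
    """Smooth per-gene occupancy: Gaussian bumps at the architecture's
    centres over a constant baseline, peak height 1."""
    centers = gene_architecture(spec, rng)
    x = np.arange(OFFSET_MIN, OFFSET_MIN + WINDOW_LENGTH, dtype=float)
    occ = np.full(WINDOW_LENGTH, baseline)
    for c in centers:
        occ += np.exp(-0.5 * ((x - c) / bump_sd) ** 2)
    return occ


def simulate_null_groups(spec: SyntheticSpec, rng: np.random.Generator,
                         n_genes: int = 12, noise_sd: float = 0.1
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Two-condition normalized profiles with no condition effect.

    Each gene gets one occupancy curve; both conditions are that curve
    plus independent i.i.d. Gaussian noise (equal means), truncated at 0
    and sum-normalized.  The per-offset paired t-test should reject at
    its nominal rate on this data.
    """
    ctrl = np.empty((n_genes, WINDOW_LENGTH))
    myo = np.empty((n_genes, WINDOW_LENGTH))
    for g in range(n_genes):
        occ = occupancy_curve(spec, rng)
        for out in (ctrl, myo):
            noisy = np.clip(occ + rng.normal(0, noise_sd, WINDOW_LENGTH), 0, None)
            out[g] = noisy / noisy.sum()
    return ctrl, myo


# ---------------------------------------------------------------------------
# ChIP

def simulate_chip(spec: SyntheticSpec, gene: GeneRecord, condition: str,
                  rng: np.random.Generator,
                  centers: np.ndarray | None = None
                  ) -> tuple[pd.DataFrame, pd.DataFrame, list[tuple[int, int]]]:
    """(IP fragments, input fragments, true site intervals) for one gene.

    The input library follows the MNase nucleosome architecture; the IP
    library is the same sampling density multiplied by ``fold`` inside
    every enrichment box that applies to the gene's group and the given
    condition (implemented by importance resampling of candidate
    positions).
    """
    if centers is None:
        centers = gene_architecture(spec, rng, group=gene.group)
    weights = np.ones_like(centers)
    n = spec.chip_depth
    boxes = [b for b in spec.chip_boxes
             if b.group == gene.group and b.condition == condition]
    true_sites = [(b.start, b.end) for b in boxes]
    if n == 0:
        empty = pd.DataFrame(columns=FRAGMENT_COLUMNS)
        return empty, empty, true_sites

    input_pos = _sample_positions(centers, weights, n, spec, rng)
    # candidates for the IP: oversample, then resample by enrichment weight
    m = 4 * n
    cand = _sample_positions(centers, weights, m, spec, rng)
    w = np.ones(m)
    for b in boxes:
        w[(cand >= b.start) & (cand <= b.end)] *= b.fold
    ip_pos = cand[rng.choice(m, size=n, p=w / w.sum())]

    ip = _positions_to_fragments(ip_pos, _fragment_lengths(spec, n, rng),
                                 gene, spec)
    inp = _positions_to_fragments(input_pos, _fragment_lengths(spec, n, rng),
                                  gene, spec)
    return ip, inp, true_sites


# ---------------------------------------------------------------------------
# full dataset

@dataclass
class SimulatedDataset:
    spec: SyntheticSpec
    records: list[GeneRecord]
    groups: dict[str, list[str]]
    mnase_fragments: dict[str, pd.DataFrame]        # condition -> fragments
    #: (kind in {ip, input}, condition, replicate in {1, 2}) -> fragments
    chip_fragments: dict[tuple[str, str, int], pd.DataFrame]
    truth: list[dict]
    chrom_sizes: dict[str, int]


def simulate_experiment(spec: SyntheticSpec,
                        rng: np.random.Generator) -> SimulatedDataset:
    """A full two-condition MNase + ChIP dataset with shared per-gene
    architectures and planted ground truth.

    ChIP libraries are emitted as two independent replicates per
    condition (two independent experiments), enabling replicate
    validation of called sites.
    """
    records, groups = synthetic_annotation(spec)
    sizes = chrom_sizes(spec, records)
    mnase: dict[str, list[pd.DataFrame]] = {"control": [], "myotube": []}
    chip: dict[tuple[str, str, int], list[pd.DataFrame]] = {
        (kind, cond, rep): []
        for kind in ("ip", "input")
        for cond in ("control", "myotube")
        for rep in (1, 2)
    }
    truth: list[dict] = []
    for gene in records:
        centers = gene_architecture(spec, rng, group=gene.group)
        for cond in ("control", "myotube"):
            frags, t = simulate_promoter_fragments(spec, gene, cond, rng,
                                                   centers=centers)
            mnase[cond].append(frags)
            truth.append(t)
        for cond in ("control", "myotube"):
            for rep in (1, 2):
                ip, inp, sites = simulate_chip(spec, gene, cond, rng,
                                               centers=centers)
                chip[("ip", cond, rep)].append(ip)
                chip[("input", cond, rep)].append(inp)
            truth.append({"gene_id": gene.gene_id, "condition": cond,
                          "chip_sites": sites})
    return SimulatedDataset(
        spec=spec, records=records, groups=groups,
        mnase_fragments={c: pd.concat(v, ignore_index=True)
                         for c, v in mnase.items()},
        chip_fragments={k: pd.concat(v, ignore_index=True)
                        for k, v in chip.items()},
        truth=truth, chrom_sizes=sizes)
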