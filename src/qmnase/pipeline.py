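"""End-to-end orchestration: simulate -> coverage -> profiles -> per-bp
tests -> regions -> fits -> correlations -> ChIP calls -> report bundle.

A run is driven by a single :class:`RunConfig`; identical configs (and
seeds) reproduce byte-identical output tables, recorded in a manifest
with content hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

import qmnase
from qmnase.annotation import GeneRecord, promoter_window, to_relative_frame
from qmnase.chip import (
    binding_value,
    call_4sigma,
    nucleosome_change_at_sites,
    site_census,
    site_region_overlap,
    site_retention,
    validated_sites,
)
from qmnase.coverage import CoverageTrack, center_coverage, size_filter
from qmnase.dynamics import (
    OFFSET_MIN,
    CoverageProfile,
    DeltaResult,
    RegionCall,
    call_regions,
    classify_regions,
    delta_profile,
    group_anova,
    normalize_profile,
    per_bp_paired_test,
    promoter_summary,
    regions_to_frame,
)
from qmnase.regression import fit_constrained_spline, fit_two_lorentzians, n_coarse_peaks
from qmnase.simulate import SimulatedDataset, SyntheticSpec, demo_spec, simulate_experiment

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """All stage parameters of an end-to-end run.

    Defaults are the method's published operating point: 130-200 bp
    fragment filter, 1-bp windows over -3000..+999, per-window
    alpha = 0.05 (uncorrected), 4-sigma ChIP seeds with 1-sigma
    extension, skeletal group as the reference whose regions anchor the
    cross-group correlations.
    """

    out_dir: str = "qmnase_run"
    seed: int = 17
    min_fragment_len: int = 130
    max_fragment_len: int = 200
    alpha: float = 0.05
    bh_correction: bool = False
    max_gap: int = 25
    min_width: int = 10
    pairing_distance: int = 300
    seed_sigma: float = 4.0
    extend_sigma: float = 1.0
    reference_group: str = "skeletal"
    fit_regions: bool = True

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


@dataclass
class CorrelationReport:
    """Pearson R between group-mean delta-profiles, per region and
    over the whole promoter."""

    per_region: dict[str, pd.DataFrame]   # region label -> symmetric R matrix
    whole_promoter: pd.DataFrame
    strong_threshold: float = 0.7

    def strong_pairs(self) -> pd.DataFrame:
        rows = []
        for label, mat in self.per_region.items():
            for a in mat.index:
                for b in mat.columns:
                    if a < b and abs(mat.loc[a, b]) > self.strong_threshold:
                        rows.append({"region": label, "group_a": a,
                                     "group_b": b, "R": mat.loc[a, b]})
        return pd.DataFrame(rows, columns=["region", "group_a", "group_b", "R"])


def _safe_corr(u: np.ndarray, v: np.ndarray) -> float:
    if np.std(u) == 0 or np.std(v) == 0:
        return float("nan")
    return float(np.corrcoef(u, v)[0, 1])


def correlate_groups(deltas: Mapping[str, DeltaResult],
                     regions: Sequence[RegionCall],
                     strong_threshold: float = 0.7) -> CorrelationReport:
    """Pearson R of group-mean delta vectors, restricted to each called
    region and over the full 4000 offsets.

    Matrices are symmetric with unit diagonal; a zero-variance vector in
    a region gives NaN for its pairs.
    """
    labels = list(deltas)
    if len(labels) < 2:
        raise PipelineError("correlate_groups needs >= 2 groups")
    means = {k: deltas[k].mean for k in labels}

    def matrix(sl: slice) -> pd.DataFrame:
        mat = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    r = _safe_corr(means[a][sl], means[b][sl])
                    mat.iloc[i, j] = mat.iloc[j, i] = r
        return mat

    per_region = {}
    for r in regions:
        sl = slice(r.start - OFFSET_MIN, r.end - OFFSET_MIN + 1)
        per_region[r.label or f"{r.start}:{r.end}"] = matrix(sl)
    whole = matrix(slice(None))
    return CorrelationReport(per_region=per_region, whole_promoter=whole,
                             strong_threshold=strong_threshold)


# ---------------------------------------------------------------------------
# profile extraction

def extract_profiles(track: CoverageTrack, records: Sequence[GeneRecord],
                     condition: str) -> dict[str, CoverageProfile]:
    """Per-gene normalized promoter profiles from a coverage track."""
    out: dict[str, CoverageProfile] = {}
    for g in records:
        w = promoter_window(g)
        dense = track.dense(g.chrom, w.start, w.end)
        values = to_relative_frame(dense, g.strand)
        out[g.gene_id] = normalize_profile(
            CoverageProfile(g.gene_id, condition, values))
    return out


def profiles_matrix(profiles: Mapping[str, CoverageProfile],
                    gene_ids: Sequence[str]) -> np.ndarray:
    return np.vstack([profiles[g].values for g in gene_ids])


# ---------------------------------------------------------------------------
# the full run

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(cfg: RunConfig,
                 spec: SyntheticSpec | None = None) -> dict:
    """Execute the whole analysis on a simulated dataset and write the
    report bundle (TSV tables + manifest) under ``cfg.out_dir``.

    Stages: simulation, fragment filtering and centre coverage, profile
    extraction, per-group per-bp paired tests, region calling and
    classification in the reference group, model fits of the reference
    delta-profile regions, cross-group correlations over those regions,
    ChIP 4-sigma site calling with census / retention / overlap reports,
    promoter summaries and group ANOVA.  Returns the manifest dict.
    """
    spec = spec if spec is not None else demo_spec()
    rng = np.random.default_rng(cfg.seed)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        data = simulate_experiment(spec, rng)

        stage = "coverage"
        tracks: dict[str, CoverageTrack] = {}
        for cond, frags in data.mnase_fragments.items():
            kept = size_filter(frags, cfg.min_fragment_len, cfg.max_fragment_len)
            tracks[cond] = center_coverage(kept, chrom_sizes=data.chrom_sizes)
        chip_tracks: dict[tuple[str, str, int], CoverageTrack] = {}
        for key, frags in data.chip_fragments.items():
            kept = size_filter(frags, cfg.min_fragment_len, cfg.max_fragment_len)
            chip_tracks[key] = center_coverage(kept, chrom_sizes=data.chrom_sizes)

        stage = "profiles"
        profiles = {cond: extract_profiles(tracks[cond], data.records, cond)
                    for cond in ("control", "myotube")}

        stage = "diff"
        deltas: dict[str, DeltaResult] = {}
        delta_frames = []
        for label, gene_ids in data.groups.items():
            ctrl = profiles_matrix(profiles["control"], gene_ids)
            myo = profiles_matrix(profiles["myotube"], gene_ids)
            d = per_bp_paired_test(ctrl, myo, group=label, alpha=cfg.alpha,
                                   bh=cfg.bh_correction)
            deltas[label] = d
            frame = d.to_frame()
            frame.insert(0, "group", label)
            delta_frames.append(frame)
        _write(pd.concat(delta_frames, ignore_index=True),
               out / "delta_profile.tsv")

        stage = "regions"
        ref = deltas[cfg.reference_group]
        regions = classify_regions(
            call_regions(ref, max_gap=cfg.max_gap, min_width=cfg.min_width),
            pairing_distance=cfg.pairing_distance)
        _write(regions_to_frame(regions), out / "regions.tsv")

        stage = "fit"
        fit_rows = []
        if cfg.fit_regions:
            x_all = np.arange(OFFSET_MIN, OFFSET_MIN + len(ref.mean))
            for r in regions:
                pad = 100
                sl = slice(max(0, r.start - OFFSET_MIN - pad),
                           min(len(ref.mean), r.end - OFFSET_MIN + 1 + pad))
                x, y = x_all[sl], ref.mean[sl]
                if n_coarse_peaks(x, y) <= 2:
                    fit = fit_two_lorentzians(x, y)
                    fit_rows.append({
                        "region": r.label, "model": "two_lorentzians",
                        "param_1": fit.amplitudes[0], "param_2": fit.centers[0],
                        "param_3": fit.gammas[0], "param_4": fit.amplitudes[1],
                        "param_5": fit.centers[1], "param_6": fit.gammas[1],
                        "baseline": fit.baseline, "rss": fit.rss,
                        "r_squared": fit.r_squared,
                    })
                else:
                    n_knots = max(8, min(40, x.size // 4))
                    fit = fit_constrained_spline(x, y, n_knots=n_knots)
                    fit_rows.append({
                        "region": r.label, "model": "constrained_spline",
                        "param_1": fit.lam, "param_2": fit.edf,
                        "param_3": float("nan"), "param_4": float("nan"),
                        "param_5": float("nan"), "param_6": float("nan"),
                        "baseline": float("nan"), "rss": fit.rss,
                        "r_squared": float("nan"),
                    })
        _write(pd.DataFrame(fit_rows, columns=[
            "region", "model", "param_1", "param_2", "param_3", "param_4",
            "param_5", "param_6", "baseline", "rss", "r_squared"]),
            out / "fits.tsv")

        stage = "correlate"
        report = correlate_groups(deltas, regions)
        corr_rows = []
        for label, mat in list(report.per_region.items()) + [("whole_promoter",
                                                              report.whole_promoter)]:
            for a in mat.index:
                for b in mat.columns:
                    if a < b:
                        corr_rows.append({"region": label, "group_a": a,
                                          "group_b": b,
                                          "R": float(mat.loc[a, b])})
        _write(pd.DataFrame(corr_rows), out / "correlations.tsv")

        stage = "chip-call"
        chip_profiles = {key: extract_profiles(t, data.records, key[1])
                         for key, t in chip_tracks.items()}
        sites_by_cond: dict[str, list] = {}
        for cond in ("control", "myotube"):
            per_rep: dict[int, list] = {1: [], 2: []}
            for rep in (1, 2):
                for g in data.records:
                    bv = binding_value(
                        chip_profiles[("ip", cond, rep)][g.gene_id],
                        chip_profiles[("input", cond, rep)][g.gene_id])
                    per_rep[rep].extend(
                        call_4sigma(bv, seed_sigma=cfg.seed_sigma,
                                    extend_sigma=cfg.extend_sigma))
            # a validated site passes the threshold in both replicates
            sites_by_cond[cond] = validated_sites(per_rep[1], per_rep[2])
        all_sites = sites_by_cond["control"] + sites_by_cond["myotube"]
        _write(pd.DataFrame(
            [(s.gene_id, s.condition, s.start, s.end, s.peak_value,
              s.sigma_multiple) for s in all_sites],
            columns=["gene_id", "condition", "start", "end", "peak_value",
                     "sigma_multiple"]), out / "sites.tsv")
        _write(site_census(all_sites, data.groups), out / "census.tsv")
        retention = site_retention(sites_by_cond["control"],
                                   sites_by_cond["myotube"])
        delta_by_gene = {
            g.gene_id: delta_profile(profiles["control"][g.gene_id],
                                     profiles["myotube"][g.gene_id])
            for g in data.records}
        _write(nucleosome_change_at_sites(all_sites, delta_by_gene),
               out / "site_delta_content.tsv")
        overlap = site_region_overlap(all_sites, regions)
        _write(overlap["sites"], out / "site_region_overlap.tsv")

        stage = "summary"
        summaries = [promoter_summary(profiles["control"][g.gene_id],
                                      profiles["myotube"][g.gene_id])
                     for g in data.records]
        summary_df = pd.DataFrame(summaries)
        gene_group = {g.gene_id: g.group for g in data.records}
        summary_df.insert(1, "group", summary_df["gene_id"].map(gene_group))
        _write(summary_df, out / "promoter_summary.tsv")
        anova = group_anova({
            label: summary_df.loc[summary_df["group"] == label,
                                  "delta_spacing"].to_numpy()
            for label in data.groups})
        anova_df = anova["pairwise"].copy()
        anova_df.insert(0, "F", anova["F"])
        anova_df.insert(1, "anova_p", anova["p"])
        _write(anova_df, out / "anova.tsv")
    except Exception as exc:
        manifest = {"status": "failed", "stage": stage, "error": str(exc),
                    "config": dataclasses.asdict(cfg)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc

    tables = sorted(p.name for p in out.glob("*.tsv"))
    manifest = {
        "status": "ok",
        "version": qmnase.__version__,
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "n_sites": {c: len(v) for c, v in sites_by_cond.items()},
        "retention": {k: retention[k] for k in ("n_retained", "n_lost",
                                                "n_gained")},
        "n_regions": len(regions),
        "tables": {name: _sha256(out / name) for name in tables},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest
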