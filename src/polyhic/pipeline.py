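"""End-to-end two-condition (WT vs KO) comparison.

`run_comparison` drives every stage in the order the biology suggests:
matrix balancing, compartments and compartment strength, distance-decay
curves, insulation and differential-insulation calling, loop/TAD pileups,
boundary violation, gene and loop classification, expression coupling and
distance statistics. All thresholds live in :class:`PipelineConfig`, the
single source every stage reads from. Given a config and seeds the run is
deterministic and the JSON summary byte-identical across repeats.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .binning import GenomeBinning, Track
from . import simulate as sim
from .contact import ContactMatrix, ice_balance, coarsen, read_contacts
from .compartments import eigenvector_compartments, compartment_strength
from .decay import rcp_curve, rcp_compare, rcp_slope, DEFAULT_RANGES
from .insulation import insulation_track, call_differential_insulation, \
    insulation_heatmap
from .aggregates import loop_pileup, tad_pileup, tad_boundary_violation
from .features import classify_tss, classify_loops, bifurcate_loops, \
    loop_geometry, distance_to_nearest, rank_sum_less, \
    compartment_track_from_labels
from .quantify import differential_expression

__all__ = ["PipelineConfig", "run_comparison", "report", "write_summary"]

STAGES = ("inputs", "balance", "compartments", "rcp", "insulation",
          "classification", "pileups", "tads", "distances", "summary")


@dataclass
class PipelineConfig:
    """All analysis constants in one place (the paper-facing defaults)."""

    fixture_dir: str | None = None     # directory with simulated/real inputs
    # balancing
    balance_tol: float = 1e-5
    mad_max: float = 5.0
    # insulation
    insulation_window: int = 250_000   # sliding square, at the matrix binsize
    delta_threshold: float = 0.2
    score_floor: float = -0.2
    exclude_above: float | None = None  # strict -1 cutoff, off by default
    heatmap_flank: int = 300_000
    # compartments
    compartment_binsize: int = 250_000
    strength_quantile: float = 0.2
    strength_min_dist: float = 2e6
    # pileups
    pileup_window_bins: int = 21       # 105 kb at 5 kb resolution
    tad_rescale_bins: int = 40
    max_tad_separation: int = 4
    # classification / expression
    tss_window: int = 3_000
    de_alpha: float = 0.05
    de_lfc: float = 0.5
    de_min_count: int = 10
    # RCP
    rcp_ranges: tuple = DEFAULT_RANGES
    rcp_bins_per_decade: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "rcp_ranges" in data:
            data["rcp_ranges"] = tuple(
                (float(lo), float(hi)) for lo, hi in data["rcp_ranges"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["rcp_ranges"] = [[float(lo), float(hi) if np.isfinite(hi) else 1e18]
                           for lo, hi in self.rcp_ranges]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def _load_inputs(config: PipelineConfig) -> dict:
    """Fixture directory if given, otherwise an in-memory default simulation."""
    if config.fixture_dir is not None:
        return sim.read_fixture(config.fixture_dir)
    truth = sim.default_truth(seed=config.seed)
    params = sim.SimulationParams(seed=config.seed)
    data = {"truth": truth, "binning": truth.binning,
            "contacts_wt": sim.simulate_contact_matrix(truth, params, "WT"),
            "contacts_ko": sim.simulate_contact_matrix(truth, params, "KO")}
    feats = sim.simulate_features(truth, truth.binning, seed=config.seed)
    for k, v in feats.items():
        data["genes" if k == "genes" else f"peaks_{k}"] = v
    data["tads"] = truth.tad_intervals("WT")
    data["tads"].columns = ["chrom", "start", "end"]
    data["loops"] = truth.loop_intervals()
    counts, _, _ = sim.simulate_expression(truth, seed=config.seed)
    data["counts"] = counts
    return data


def _coverage_track(binning: GenomeBinning, peaks: pd.DataFrame,
                    label: str) -> Track:
    """bp of peak coverage per bin — orientation reference for compartments."""
    values = np.zeros(binning.n_bins)
    for p in peaks.itertuples(index=False):
        if p.chrom not in binning.chromsizes:
            continue
        off = binning.chrom_offset(p.chrom)
        b0 = binning.bin_index(p.chrom, p.start)
        b1 = binning.bin_index(p.chrom, min(p.end - 1,
                                            binning.chromsizes[p.chrom] - 1))
        for b in range(b0, b1 + 1):
            lo = max(p.start, b * binning.binsize)
            hi = min(p.end, (b + 1) * binning.binsize)
            values[off + b] += hi - lo
    return Track(binning, values, label=label)


def run_comparison(config: PipelineConfig) -> dict:
    """Run the full WT-vs-KO comparison; returns the result bundle.

    The bundle maps stage names to their objects plus a JSON-serialisable
    ``summary``. Any stage failure raises with the stage name attached.
    """
    bundle = {"config": config}
    stage = "inputs"
    try:
        data = _load_inputs(config)
        bundle["inputs"] = data
        bn = data["binning"]
        cm = {"WT": data["contacts_wt"], "KO": data["contacts_ko"]}

        stage = "balance"
        balance_info = {c: ice_balance(cm[c], tol=config.balance_tol,
                                       mad_max=config.mad_max)
                        for c in cm}

        stage = "compartments"
        factor = max(1, config.compartment_binsize // bn.binsize)
        coarse = {}
        for c in cm:
            coarse[c] = coarsen(cm[c], factor)
            ice_balance(coarse[c], tol=config.balance_tol,
                        mad_max=config.mad_max)
        orientation = _coverage_track(coarse["WT"].binning,
                                      data.get("peaks_h3k27ac",
                                               pd.DataFrame(columns=["chrom", "start", "end"])),
                                      "active_coverage")
        comp = {c: eigenvector_compartments(coarse[c], orientation) for c in cm}
        strength = {c: compartment_strength(
            coarse[c], comp[c], quantile=config.strength_quantile,
            min_dist=config.strength_min_dist) for c in cm}
        bundle["compartments"] = {"tracks": comp, "strength": strength,
                                  "coarse": coarse}

        stage = "rcp"
        max_dist = min(int(0.6 * max(bn.chromsizes.values())), 30_000_000)
        curves = {c: rcp_curve(cm[c], max_dist=max_dist,
                               bins_per_decade=config.rcp_bins_per_decade,
                               label=c) for c in cm}
        ratios = rcp_compare(curves["WT"], curves["KO"], config.rcp_ranges)
        slopes = {c: rcp_slope(curves[c]) for c in cm}
        bundle["rcp"] = {"curves": curves, "ratios": ratios, "slopes": slopes}

        stage = "insulation"
        ins = {c: insulation_track(cm[c], window=config.insulation_window)
               for c in cm}
        calls, regions = call_differential_insulation(
            ins["WT"], ins["KO"], delta_threshold=config.delta_threshold,
            score_floor=config.score_floor, exclude_above=config.exclude_above)
        gain = regions[regions["category"] == "gain"].reset_index(drop=True)
        loss = regions[regions["category"] == "loss"].reset_index(drop=True)
        heat = insulation_heatmap(regions, {"WT": ins["WT"], "KO": ins["KO"]},
                                  flank=config.heatmap_flank) if len(regions) \
            else None
        bundle["insulation"] = {"tracks": ins, "calls": calls,
                                "regions": regions, "heatmap": heat}

        stage = "classification"
        genes = classify_tss(
            data["genes"], data["peaks_biocap"], data["peaks_ring1b"],
            data["peaks_suz12"], window=config.tss_window,
            chromsizes=bn.chromsizes)
        de = differential_expression(
            data["counts"],
            ["wt" if c.startswith("wt") else "ko" for c in data["counts"].columns],
            lfc_threshold=config.de_lfc, alpha=config.de_alpha,
            min_count=config.de_min_count)
        genes = genes.merge(
            de["status"].rename("de_status"), left_on="gene_id",
            right_index=True, how="left")
        genes["de_status"] = genes["de_status"].fillna("untested")
        loops = classify_loops(data["loops"].rename(columns=str),
                               data["peaks_ring1b"], genes,
                               window=config.tss_window)
        loops = bifurcate_loops(loops, genes, window=config.tss_window)
        bundle["classification"] = {"genes": genes, "loops": loops, "de": de}

        stage = "pileups"
        window = config.pileup_window_bins * bn.binsize
        pile = {}
        groups = {
            "nonpcg": loops[loops["pcg_class"] == "nonpcg"],
            "pcg": loops[loops["pcg_class"].isin(["pcg", "prc1prc2"])],
            "prc1prc2": loops[loops["pcg_class"] == "prc1prc2"],
            "up": loops[loops["bifurcation"] == "up"],
            "not_up": loops[loops["bifurcation"] == "not_up"],
        }
        for name, sub in groups.items():
            if len(sub) == 0:
                continue
            try:
                pile[name] = {c: loop_pileup(cm[c], sub, window=window)
                              for c in cm}
            except ValueError as e:
                warnings.warn(f"pileup group {name!r} skipped: {e}")
        bundle["pileups"] = pile

        stage = "tads"
        tads = data["tads"]
        tadpile = {c: tad_pileup(cm[c], tads,
                                 rescale_bins=config.tad_rescale_bins)
                   for c in cm}
        violation = {c: tad_boundary_violation(
            cm[c], tads, max_n=config.max_tad_separation) for c in cm}
        change = {n: violation["KO"][n] - violation["WT"][n]
                  for n in violation["WT"]}
        bundle["tads"] = {"pileup": tadpile, "violation": violation,
                          "change": change}

        stage = "distances"
        dist = genes[["gene_id", "chrom", "tss", "gene_class",
                      "de_status"]].copy()
        if len(gain):
            dist["distance"] = distance_to_nearest(dist, gain)
            focal = dist[(dist["gene_class"] == "prc1prc2")
                         & (dist["de_status"] == "up")]["distance"]
            others = dist[~((dist["gene_class"] == "prc1prc2")
                            & (dist["de_status"] == "up"))]["distance"]
            pval = rank_sum_less(focal, others)
        else:
            dist["distance"] = np.nan
            focal = others = pd.Series(dtype=float)
            pval = np.nan
        bundle["distances"] = {"table": dist, "rank_sum_p": pval}

        stage = "summary"
        bundle["summary"] = _summarise(bundle, balance_info)
        return bundle
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err


def _summarise(bundle: dict, balance_info: dict) -> dict:
    cm = {"WT": bundle["inputs"]["contacts_wt"],
          "KO": bundle["inputs"]["contacts_ko"]}
    genes = bundle["classification"]["genes"]
    loops = bundle["classification"]["loops"]
    de = bundle["classification"]["de"]
    regions = bundle["insulation"]["regions"]
    calls = bundle["insulation"]["calls"]
    pile = bundle["pileups"]
    summary = {
        "seed": bundle["config"].seed,
        "totals": {c: cm[c].total() for c in cm},
        "balance": {c: {ch: d["n_iter"] for ch, d in balance_info[c].items()}
                    for c in balance_info},
        "compartment_strength": {
            c: bundle["compartments"]["strength"][c]["genome"] for c in cm},
        "rcp_log2_ratio": bundle["rcp"]["ratios"],
        "rcp_slope": bundle["rcp"]["slopes"],
        "insulation": {
            "n_gain_regions": int((regions["category"] == "gain").sum()),
            "n_loss_regions": int((regions["category"] == "loss").sum()),
            "n_gain_bins": int((calls["category"] == "gain").sum()),
            "n_loss_bins": int((calls["category"] == "loss").sum()),
            "n_eligible_bins": int(
                calls["category"].isin(["gain", "loss", "unchanged"]).sum()),
        },
        "gene_classes": genes["gene_class"].value_counts().to_dict(),
        "loop_classes": loops["pcg_class"].value_counts().to_dict(),
        "bifurcation": loops["bifurcation"].value_counts().to_dict(),
        "de": de["status"].value_counts().to_dict(),
        "pileup_enrichment": {
            name: {c: res[c].enrichment for c in res}
            for name, res in pile.items()},
        "pileup_ko_wt_ratio": {
            name: res["KO"].enrichment / res["WT"].enrichment
            for name, res in pile.items()},
        "boundary_violation_change": {
            str(n): v for n, v in bundle["tads"]["change"].items()},
        "distance_rank_sum_p": bundle["distances"]["rank_sum_p"],
    }
    return _round_floats(summary)


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        x = float(obj)
        return round(x, ndigits) if np.isfinite(x) else None
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    return obj


def write_summary(bundle: dict, path) -> None:
    Path(path).write_text(json.dumps(bundle["summary"], indent=1,
                                     sort_keys=True) + "\n")


def report(bundle: dict, outdir, figures: bool = True) -> list:
    """Write tables, tracks and figures from a completed bundle.

    Returns the list of files written; a bundle missing stages raises with
    the missing stage names.
    """
    missing = [s for s in ("inputs", "compartments", "rcp", "insulation",
                           "classification", "pileups", "tads", "distances",
                           "summary") if s not in bundle]
    if missing:
        raise ValueError(f"incomplete bundle; missing stages: {missing}")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    files = []

    def _w(path):
        files.append(path)
        return path

    write_summary(bundle, _w(out / "summary.json"))
    for cond in ("WT", "KO"):
        tr = bundle["insulation"]["tracks"][cond]
        tr.write_bedgraph(_w(out / f"insulation_{cond.lower()}.bedgraph"))
        ev = bundle["compartments"]["tracks"][cond].track
        ev.write_bedgraph(_w(out / f"eigenvector_{cond.lower()}.bedgraph"))
    calls = bundle["insulation"]["calls"]
    calls.to_csv(_w(out / "insulation_calls.tsv"), sep="\t", index=False)
    regions = bundle["insulation"]["regions"]
    for cat in ("gain", "loss"):
        sub = regions[regions["category"] == cat]
        sub[["chrom", "start", "end"]].to_csv(
            _w(out / f"insulation_{cat}.bed"), sep="\t", header=False,
            index=False)
    bundle["classification"]["genes"].to_csv(
        _w(out / "gene_classes.tsv"), sep="\t", index=False)
    bundle["classification"]["loops"].to_csv(
        _w(out / "loop_classes.tsv"), sep="\t", index=False)
    bundle["classification"]["de"].to_csv(_w(out / "de_results.tsv"), sep="\t")
    bundle["distances"]["table"].to_csv(
        _w(out / "tss_distances.tsv"), sep="\t", index=False)
    viol = pd.DataFrame(bundle["tads"]["violation"])
    viol["change"] = pd.Series(bundle["tads"]["change"])
    viol.rename_axis("n_separation").to_csv(
        _w(out / "boundary_violation.tsv"), sep="\t")
    lines = ["# Two-condition Hi-C comparison", ""]
    s = bundle["summary"]
    lines += [f"- compartment strength: WT {s['compartment_strength']['WT']}, "
              f"KO {s['compartment_strength']['KO']}",
              f"- insulation: {s['insulation']['n_gain_regions']} gain / "
              f"{s['insulation']['n_loss_regions']} loss regions",
              f"- RCP log2 KO/WT per range: {s['rcp_log2_ratio']}",
              f"- loop pileup KO/WT enrichment ratios: {s['pileup_ko_wt_ratio']}",
              f"- DE: {s['de']}"]
    (_w(out / "report.md")).write_text("\n".join(lines) + "\n")
    if figures:
        files += _figures(bundle, out)
    return files


def _figures(bundle: dict, out: Path) -> list:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    # RCP curves
    fig, ax = plt.subplots(figsize=(4, 3))
    for cond, curve in bundle["rcp"]["curves"].items():
        ok = curve.prob > 0
        ax.loglog(curve.centers[ok], curve.prob[ok], label=cond)
    ax.set_xlabel("genomic distance (bp)")
    ax.set_ylabel("relative contact probability")
    ax.legend(frameon=False)
    fig.tight_layout()
    p = out / "rcp.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)
    # pileups
    pile = bundle["pileups"]
    if pile:
        fig, axes = plt.subplots(2, len(pile), figsize=(2.2 * len(pile), 4.6),
                                 squeeze=False)
        for j, (name, res) in enumerate(pile.items()):
            for i, cond in enumerate(("WT", "KO")):
                ax = axes[i][j]
                ax.imshow(res[cond].matrix, cmap="RdBu_r", vmin=0, vmax=3)
                ax.set_title(f"{name} {cond}\n{res[cond].enrichment:.2f}",
                             fontsize=8)
                ax.set_xticks([])
                ax.set_yticks([])
        fig.tight_layout()
        p = out / "pileups.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    # insulation heatmap
    heat = bundle["insulation"]["heatmap"]
    if heat is not None:
        fig, axes = plt.subplots(1, 2, figsize=(6, 3), sharey=True)
        for ax, cond in zip(axes, ("WT", "KO")):
            ax.imshow(heat.matrices[cond], aspect="auto", cmap="RdBu_r",
                      vmin=-1.5, vmax=1.5)
            ax.set_title(cond)
            ax.set_xlabel("offset (bins)")
        fig.tight_layout()
        p = out / "insulation_heatmap.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written
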