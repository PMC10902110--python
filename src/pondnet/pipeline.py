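"""End-to-end orchestration: landscape -> resistance -> current -> stats.

A single global seed deterministically derives per-stage seeds, so a
re-run with the same configuration reproduces every artifact bit for
bit. Each stage logs its cell/site counts and the manifest records
seeds, timings and SHA-256 checksums of everything written.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import circuit, metrics as metrics_mod, resistance, stats as stats_mod, synthetic

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

logger = logging.getLogger("pondnet")

STAGES = ("landscape", "resistance", "buffer", "current", "metrics", "community", "stats")


@dataclass
class RunConfig:
    """Configuration of a full synthetic pipeline run.

    The defaults are the canonical analysis settings: 10 m cells, a
    15 km representative buffer at the 14.2/34.8/51.0 low/medium/high
    ratio, 50 perimeter nodes solved in all-pairs mode on the
    8-neighbour graph, 900 m / 300 m taxon scales and 999 permutations.
    Scale grids and the buffer down for demonstrations; the statistical
    contracts do not depend on the raster size.
    """

    landscape: synthetic.LandscapeConfig = field(default_factory=synthetic.LandscapeConfig)
    community: synthetic.CommunityConfig = field(default_factory=synthetic.CommunityConfig)
    n_stormwater: int = 41
    n_natural: int = 8
    buffer_width_m: float = 15_000.0
    target_ratio: tuple[float, float, float] = (0.142, 0.348, 0.510)
    n_nodes: int = 50
    neighbourhood: int = 8
    pair_mode: str = "all"
    scales: dict | None = None  # None: derive 900/300 from the flight table
    log10_floor: float | None = 1e-12
    n_permutations: int = 999
    seed: int = 0
    output_dir: str | None = None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, stages=None) -> dict:
    """Run the pipeline and return the manifest.

    ``stages`` may name a subset of :data:`STAGES`; execution runs from
    the start and stops after the last stage named. Artifacts are
    written under ``config.output_dir`` when set; computed objects are
    returned in the manifest under ``"results"``.
    """
    if stages is None:
        stop_after = STAGES[-1]
    else:
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        stop_after = max(stages, key=STAGES.index)

    ss = np.random.SeedSequence(config.seed)
    stage_seeds = {name: int(child.generate_state(1)[0] % (2**31 - 1)) for name, child in zip(STAGES, ss.spawn(len(STAGES)))}

    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "config": {
            **{k: v for k, v in asdict(config).items() if k not in ("landscape", "community")},
            "landscape": asdict(config.landscape),
            "community": asdict(config.community),
        },
        "stage_seeds": stage_seeds,
        "timings_s": {},
        "checksums": {},
        "counts": {},
        "results": {},
    }
    results = manifest["results"]
    files: list[Path] = []

    def _stage(name):
        t0 = time.perf_counter()
        return t0

    def _done(name, t0, **counts):
        manifest["timings_s"][name] = round(time.perf_counter() - t0, 4)
        manifest["counts"].update(counts)
        logger.info("stage %s done in %.2fs %s", name, manifest["timings_s"][name], counts)

    try:
        # ---- landscape
        t0 = _stage("landscape")
        lc_config = replace(config.landscape, seed=stage_seeds["landscape"] if config.landscape.seed is None else config.landscape.seed)
        landcover = synthetic.generate_landscape(lc_config)
        sites = synthetic.generate_sites(landcover, config.n_stormwater, config.n_natural, seed=stage_seeds["landscape"])
        results["landcover"] = landcover
        results["sites"] = sites
        if out_dir:
            landcover.write_ascii(out_dir / "landcover.asc")
            sites.to_csv(out_dir / "sites.csv", index=False)
            files += [out_dir / "landcover.asc", out_dir / "sites.csv"]
        _done("landscape", t0, n_cells=landcover.n_cells, n_sites=len(sites))
        if stop_after == "landscape":
            return _finish(manifest, files, out_dir)

        # ---- resistance
        t0 = _stage("resistance")
        rr = resistance.classify(landcover)
        results["resistance"] = rr
        if out_dir:
            rr.raster.write_ascii(out_dir / "resistance.asc")
            files.append(out_dir / "resistance.asc")
        _done("resistance", t0, resistance_proportions=resistance.resistance_proportions(rr))
        if stop_after == "resistance":
            return _finish(manifest, files, out_dir)

        # ---- buffer + perimeter nodes
        t0 = _stage("buffer")
        buffered = resistance.add_buffer(rr, config.buffer_width_m, config.target_ratio, seed=stage_seeds["buffer"])
        nodes = resistance.place_perimeter_nodes(buffered, config.n_nodes, seed=stage_seeds["buffer"])
        results["buffered"] = buffered
        results["nodes"] = nodes
        if out_dir:
            node_df = pd.DataFrame({"row": nodes.rows, "col": nodes.cols, "x": nodes.xy[:, 0], "y": nodes.xy[:, 1]})
            node_df.to_csv(out_dir / "nodes.csv", index=False)
            (out_dir / "nodes.meta.json").write_text(json.dumps({"seed": nodes.seed, "n": len(nodes)}))
            files += [out_dir / "nodes.csv", out_dir / "nodes.meta.json"]
        _done("buffer", t0, n_buffered_cells=buffered.raster.n_cells, n_nodes=len(nodes))
        if stop_after == "buffer":
            return _finish(manifest, files, out_dir)

        # ---- current map
        t0 = _stage("current")
        graph = circuit.build_graph(buffered, neighbourhood=config.neighbourhood)
        cmap = circuit.mean_current_map(graph, nodes, log10_floor=config.log10_floor, pair_mode=config.pair_mode)
        results["current_map"] = cmap
        if out_dir:
            cmap.to_raster().write_ascii(out_dir / "current_map.asc")
            files.append(out_dir / "current_map.asc")
        _done("current", t0, n_pairs=cmap.n_pairs, n_edges=graph.n_edges)
        if stop_after == "current":
            return _finish(manifest, files, out_dir)

        # ---- site metrics
        t0 = _stage("metrics")
        if config.scales is not None:
            scales = dict(config.scales)
        else:
            flights = synthetic.reference_flight_table()
            scales = {
                "Anisoptera": metrics_mod.select_scale(flights, "Anisoptera"),
                "Zygoptera": metrics_mod.select_scale(flights, "Zygoptera"),
            }
        habitat_pts = metrics_mod.raster_habitat_centroids(landcover)
        site_metrics = metrics_mod.site_metrics_table(cmap, sites, habitat_pts, scales=scales)
        site_metrics = site_metrics.merge(sites[["id", "type"]], left_on="pond_id", right_on="id").drop(columns="id")
        results["scales"] = scales
        results["site_metrics"] = site_metrics
        if out_dir:
            site_metrics.to_csv(out_dir / "site_metrics.csv", index=False)
            files.append(out_dir / "site_metrics.csv")
        _done("metrics", t0, scales=scales, n_habitat_points=len(habitat_pts))
        if stop_after == "metrics":
            return _finish(manifest, files, out_dir)

        # ---- community
        t0 = _stage("community")
        drag_scale = scales["Anisoptera"]
        msub = site_metrics[site_metrics["scale_m"] == drag_scale].reset_index(drop=True)
        comm_config = replace(
            config.community,
            n_sites=len(msub),
            seed=stage_seeds["community"] if config.community.seed is None else config.community.seed,
        )
        cm = synthetic.generate_community(msub, comm_config)
        results["community"] = cm
        if out_dir:
            out = cm.counts.copy()
            out.index.name = "pond_id"
            out.to_csv(out_dir / "community.csv")
            cm.suborder.rename_axis("species").to_csv(out_dir / "species_suborders.csv")
            files += [out_dir / "community.csv", out_dir / "species_suborders.csv"]
        _done("community", t0, n_species=cm.counts.shape[1])
        if stop_after == "community":
            return _finish(manifest, files, out_dir)

        # ---- statistics
        t0 = _stage("stats")
        glm_df, rda_df = stats_mod.run_model_battery(
            site_metrics, cm, scales=scales, n_permutations=config.n_permutations, seed=stage_seeds["stats"]
        )
        # uninformative-parameter screening: does SD of current add anything
        # beyond mean current for abundance?
        screening = []
        for suborder, scale in scales.items():
            msc = site_metrics[site_metrics["scale_m"] == scale].set_index("pond_id").loc[cm.counts.index]
            y = stats_mod.abundance(cm, suborder).to_numpy(dtype=float)
            x_red = sm.add_constant(msc[["mean_current"]].to_numpy())
            x_full = sm.add_constant(msc[["mean_current", "sd_current"]].to_numpy())
            ll_red = float(sm.OLS(y, x_red).fit().llf)
            ll_full = float(sm.OLS(y, x_full).fit().llf)
            decision = stats_mod.screen_uninformative(ll_full, ll_red)
            decision.update({"suborder": suborder, "extra_parameter": "sd_current"})
            screening.append(decision)
        # pond-type comparisons and predictor correlations per scale
        wilcoxon = []
        correlations = []
        for scale in sorted({v for v in scales.values()}):
            msc = site_metrics[site_metrics["scale_m"] == scale]
            nat = msc[msc["type"] == "natural"]
            sto = msc[msc["type"] == "stormwater"]
            for var in ("mean_current", "n_neighbours"):
                if len(nat) and len(sto):
                    res = stats_mod.wilcoxon_rank_sum(nat[var], sto[var])
                    res.update({"scale_m": scale, "variable": var})
                    wilcoxon.append(res)
            correlations.append(
                {
                    "scale_m": scale,
                    "r_mean_current_vs_n_neighbours": stats_mod.predictor_correlation(
                        msc["mean_current"], msc["n_neighbours"]
                    ),
                }
            )
        results["glm_fits"] = glm_df
        results["rda_results"] = rda_df
        results["screening"] = pd.DataFrame(screening)
        results["wilcoxon"] = pd.DataFrame(wilcoxon)
        results["correlations"] = pd.DataFrame(correlations)
        if out_dir:
            glm_df.to_csv(out_dir / "glm_fits.csv", index=False)
            rda_df.to_csv(out_dir / "rda_results.csv", index=False)
            results["screening"].to_csv(out_dir / "screening.csv", index=False)
            results["wilcoxon"].to_csv(out_dir / "wilcoxon.csv", index=False)
            results["correlations"].to_csv(out_dir / "predictor_correlations.csv", index=False)
            files += [
                out_dir / "glm_fits.csv",
                out_dir / "rda_results.csv",
                out_dir / "screening.csv",
                out_dir / "wilcoxon.csv",
                out_dir / "predictor_correlations.csv",
            ]
        _done("stats", t0, n_glm_models=len(glm_df), n_rda_models=len(rda_df))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed (last completed stages: {list(manifest['timings_s'])})") from exc

    return _finish(manifest, files, out_dir)


def _finish(manifest: dict, files: list[Path], out_dir: Path | None) -> dict:
    for f in files:
        manifest["checksums"][f.name] = _sha256(f)
    if out_dir:
        serialisable = {k: v for k, v in manifest.items() if k != "results"}
        (out_dir / "manifest.json").write_text(json.dumps(serialisable, indent=2, default=str))
    return manifest
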