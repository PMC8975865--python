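"""End-to-end extraction: DEM + thresholds -> ordered network + parameters.

Glues the stages together in the order of the processing workflow: slope
map, threshold detection, noise filtering, fragment reconnection, thinning,
spur pruning, graph building, outlet identification, reverse-Strahler
ordering and parameter extraction. Also drives whole-site runs producing
the standard output bundle (area/creek XYZ, ordered-skeleton XYC, per-order
and network CSVs, optional sensitivity and change-analysis tables).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import detect as _detect
from . import morphometrics as _morpho
from . import network as _network
from .detect import CreekMask, DetectionConfig, SkeletonGrid
from .grid import (ElevationGrid, GridDataError, MarshMask, SlopeGrid,
                   compute_slope_degrees, crop_to_marsh, fill_nodata_nearest,
                   read_ascii_grid, write_xyz)
from .morphometrics import NetworkMetrics
from .network import CreekNetwork, write_xyc
from .tides import TidalLevels, interpolate_tidal_levels, read_ports_csv

__all__ = ["ExtractionResult", "extract", "resolve_z_thresh", "run_site"]

CSV_FLOAT_FORMAT = "%.6f"


@dataclass
class ExtractionResult:
    grid: ElevationGrid
    marsh: MarshMask
    slope: SlopeGrid
    mask_raw: CreekMask
    mask_filtered: CreekMask
    mask_repaired: CreekMask
    skeleton: SkeletonGrid
    network: CreekNetwork
    metrics: NetworkMetrics
    channels: pd.DataFrame
    orders: pd.DataFrame
    log: list = field(default_factory=list)


def extract(grid: ElevationGrid, marsh: MarshMask, cfg: DetectionConfig,
            tides: TidalLevels | None = None, prune_px: int = 5,
            spacing: int = 5, fit_len: int = 5) -> ExtractionResult:
    """Run the full single-epoch extraction on a preprocessed grid."""
    log: list[str] = [f"z_thresh={cfg.z_thresh:.3f} s_thresh={cfg.s_thresh:.1f} "
                      f"min_component_px={cfg.min_component_px} "
                      f"max_repair_dist={cfg.max_repair_dist:.1f}"]
    slope = compute_slope_degrees(grid)
    raw = _detect.detect_creek_mask(grid, slope, marsh, cfg)
    if not raw.values.any():
        raise GridDataError("creek detection produced an empty mask")
    log.append(f"raw mask: {raw.n_pixels} px")
    filt = _detect.filter_small_components(raw, cfg.min_component_px)
    log.append(f"filtered mask: {filt.n_pixels} px "
               f"(removed {raw.n_pixels - filt.n_pixels})")
    if not filt.values.any():
        raise GridDataError("all creek components fell below the size filter")
    rep = _detect.reconnect_fragments(filt, cfg, cell_size=grid.cell_size)
    log.append(f"repaired mask: {rep.n_pixels} px; "
               f"{len(rep.detached)} fragment(s) left detached")
    skel = _detect.skeletonize(rep)
    skel = _detect.prune_spurs(skel, min_len_px=prune_px)
    log.append(f"skeleton: {int(skel.values.sum())} px after pruning "
               f"(spur threshold {prune_px} px)")
    net = _network.build_network(skel, cell_size=grid.cell_size)
    net = _network.identify_outlets(net, marsh, rep, grid, fit_len=fit_len)
    net = _network.assign_reverse_strahler(
        net, spur_len=prune_px * grid.cell_size)
    log.append(f"network: {net.n_segments} segments, "
               f"{len(net.channels)} channels, {len(net.outlets)} outlet(s), "
               f"{len(net.removed_segments)} cycle segment(s) removed, "
               f"{len(net.pruned_segments)} stub(s) pruned, "
               f"{len(net.unordered_components)} outlet-less component(s)")
    channels = _morpho.channel_table(grid, rep, net, spacing=spacing,
                                     fit_len=fit_len)
    if not channels.empty:
        skipped = int(channels["n_skipped"].sum())
        if skipped:
            log.append(f"{skipped} transect station(s) skipped")
    orders = _morpho.order_table(channels)
    metrics = _morpho.network_summary(grid, marsh, rep, net, tides=tides)
    return ExtractionResult(grid=grid, marsh=marsh, slope=slope, mask_raw=raw,
                            mask_filtered=filt, mask_repaired=rep,
                            skeleton=skel, network=net, metrics=metrics,
                            channels=channels, orders=orders, log=log)


def resolve_z_thresh(value, tides: TidalLevels | None) -> float:
    """An elevation threshold given absolutely (m ODN) or relative to a
    tidal level, e.g. ``{"level": "mhwn", "offset": -0.5}``."""
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, dict) and "level" in value:
        if tides is None:
            raise GridDataError(
                "z_thresh is relative to a tidal level but no tides given")
        base = getattr(tides, value["level"].lower())
        return float(base) + float(value.get("offset", 0.0))
    raise GridDataError(f"cannot interpret z_thresh specification {value!r}")


def _tides_from_config(cfg: dict) -> TidalLevels | None:
    if "tides" in cfg:
        return TidalLevels(**{k.lower(): float(v)
                              for k, v in cfg["tides"].items()})
    if "ports_csv" in cfg:
        ports = read_ports_csv(cfg["ports_csv"])
        site = tuple(cfg["site_xy"])
        return interpolate_tidal_levels(site, ports,
                                        radius=float(cfg.get("port_radius",
                                                             30_000.0)))
    return None


def run_site(cfg: dict, out_dir) -> dict:
    """Whole-site run from a config mapping; writes the output bundle.

    Config keys: ``epochs`` (list of Esri ASCII DEM paths), ``z_thresh``
    (absolute or tide-relative), ``s_thresh``, ``min_component_px``,
    ``max_repair_dist``, ``hat`` (crop level; defaults to the tidal HAT),
    ``tides`` or ``ports_csv``+``site_xy``, and flags ``sensitivity`` /
    ``change``. Returns the per-epoch results keyed by epoch stem.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    epochs = cfg["epochs"]
    if not epochs:
        raise GridDataError("config lists no input epochs")
    if cfg.get("change") and len(epochs) < 2:
        raise GridDataError("change analysis requires at least 2 epochs")
    tides = _tides_from_config(cfg)
    hat = cfg.get("hat")
    if hat is None:
        if tides is None:
            raise GridDataError("provide 'hat' or tidal levels to crop with")
        hat = tides.hat
    dcfg = DetectionConfig(
        z_thresh=resolve_z_thresh(cfg["z_thresh"], tides),
        s_thresh=float(cfg.get("s_thresh", 40.0)),
        min_component_px=int(cfg.get("min_component_px", 10)),
        max_repair_dist=float(cfg.get("max_repair_dist", 5.0)),
        z_tolerance=float(cfg.get("z_tolerance", 0.15)),
    )
    results: dict[str, ExtractionResult] = {}
    log: list[str] = []
    for epoch in epochs:
        stem = Path(epoch).stem
        boundary = cfg.get("boundary")  # closed ring of [x, y] vertices
        try:
            grid = read_ascii_grid(epoch)
            marsh = crop_to_marsh(grid, float(hat), boundary=boundary)
            grid = fill_nodata_nearest(grid, marsh)
            res = extract(grid, marsh, dcfg, tides=tides,
                          prune_px=int(cfg.get("prune_px", 5)))
        except Exception as exc:
            raise type(exc)(f"epoch '{stem}': {exc}") from exc
        results[stem] = res
        log.extend(f"[{stem}] {line}" for line in res.log)
        write_xyz(grid, marsh, out / f"{stem}_area.xyz")
        write_xyz(grid, MarshMask(values=res.mask_repaired.values),
                  out / f"{stem}_creek.xyz")
        write_xyc(res.network, grid, out / f"{stem}_skeleton.xyc")
        res.channels.to_csv(out / f"{stem}_channels.csv", index=False,
                            float_format=CSV_FLOAT_FORMAT)
        res.orders.to_csv(out / f"{stem}_orders.csv", index=False,
                          float_format=CSV_FLOAT_FORMAT)
        net_row = pd.DataFrame([res.metrics.to_dict()])
        net_row.to_csv(out / f"{stem}_network.csv", index=False,
                       float_format=CSV_FLOAT_FORMAT)
        if cfg.get("sensitivity"):
            table = _morpho.threshold_sensitivity(grid, marsh, dcfg,
                                                  tides=tides)
            table.to_csv(out / f"{stem}_sensitivity.csv", index=False,
                         float_format=CSV_FLOAT_FORMAT)
            for off, msg in table.attrs["failed_runs"]:
                log.append(f"[{stem}] sensitivity offset {off:+.2f} m "
                           f"excluded: {msg}")
    if cfg.get("change"):
        stems = [Path(e).stem for e in epochs]
        first, last = stems[0], stems[-1]
        r0, r1 = results[first], results[last]
        both = MarshMask(values=r0.marsh.values & r1.marsh.values)
        table = _morpho.elevation_change_vs_distance(
            r0.grid, r1.grid, both, r0.mask_repaired, r1.mask_repaired,
            max_dist=float(cfg.get("change_max_dist", 20.0)),
            bin_width=float(cfg.get("change_bin", 1.0)))
        table.to_csv(out / f"change_{first}_{last}.csv", index=False,
                     float_format=CSV_FLOAT_FORMAT)
    (out / "log.txt").write_text("\n".join(log) + "\n")
    return results
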