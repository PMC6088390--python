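"""File formats: TIFF stacks with JSON side-cars, CSV tables, JSON results.

Stacks travel as multi-page TIFF (pages ordered channel-major, then z) with
a JSON side-car pinning channel names, voxel spacing and optionally the
mitotic phase.  Tables are UTF-8 CSV with '.' decimal and a stable column
order.  Shell indices are 1-based and sectors are named, matching the
polar/diagonal/equatorial nomenclature used throughout.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .geometry import (
    DEFAULT_GRID,
    ImageStack,
    MitoticFrame,
    SpheriCellMap,
)
from .model import NormalizedDataset, SpeciesSet, normalize_dataset
from .stats import CellMeasures

MAP_COLUMNS = [
    "cell_id", "channel", "shell", "sector", "mean_intensity",
    "voxel_count", "volume_um3",
]


def write_stack(stack: ImageStack, path, phase: str | None = None) -> None:
    """Write a multi-page TIFF plus its JSON side-car (``<path>.json``)."""
    path = Path(path)
    pages = stack.voxels.reshape(-1, *stack.voxels.shape[2:]).astype(np.float32)
    tifffile.imwrite(path, pages)
    sidecar = {
        "channel_names": list(stack.channel_names),
        "spacing_um": list(stack.spacing),
        "n_z": int(stack.voxels.shape[1]),
    }
    if phase is not None:
        sidecar["phase"] = phase
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2)
    )


def read_stack(path, sidecar_path=None) -> ImageStack:
    """Read a TIFF + side-car pair back into an :class:`ImageStack`."""
    path = Path(path)
    sidecar_path = Path(sidecar_path) if sidecar_path else path.with_suffix(
        path.suffix + ".json"
    )
    meta = json.loads(sidecar_path.read_text())
    pages = tifffile.imread(path)
    n_channels = len(meta["channel_names"])
    n_z = int(meta["n_z"])
    if pages.shape[0] != n_channels * n_z:
        raise ValueError(
            f"TIFF has {pages.shape[0]} pages but side-car declares "
            f"{n_channels} channels x {n_z} slices"
        )
    voxels = pages.reshape(n_channels, n_z, *pages.shape[1:]).astype(float)
    return ImageStack(
        voxels=voxels,
        spacing=tuple(meta["spacing_um"]),
        channel_names=list(meta["channel_names"]),
    )


def read_phase(path) -> str:
    path = Path(path)
    meta = json.loads(
        path.with_suffix(path.suffix + ".json").read_text()
    )
    if "phase" not in meta:
        raise ValueError("side-car does not declare a mitotic phase")
    return meta["phase"]


def maps_to_frame(maps: list) -> pd.DataFrame:
    """Long-format DataFrame of one or more SpheriCellMaps (with frame
    columns so the maps round-trip)."""
    rows = []
    for mp in maps:
        fr = mp.frame
        for ci, channel in enumerate(mp.channel_names):
            for mu in range(mp.grid.n_shells):
                for nu, sector in enumerate(mp.grid.sector_names):
                    rows.append({
                        "cell_id": mp.cell_id,
                        "channel": channel,
                        "shell": mu + 1,
                        "sector": sector,
                        "mean_intensity": mp.intensities[ci, mu, nu],
                        "voxel_count": int(mp.voxel_counts[mu, nu]),
                        "volume_um3": mp.volumes[mu, nu],
                        "phase": fr.phase,
                        "center_z": fr.center[0],
                        "center_y": fr.center[1],
                        "center_x": fr.center[2],
                        "axis_z": fr.axis[0],
                        "axis_y": fr.axis[1],
                        "axis_x": fr.axis[2],
                        "sphere_radius_um": fr.sphere_radius,
                    })
    return pd.DataFrame(rows)


def write_maps(maps: list, path) -> None:
    maps_to_frame(maps).to_csv(path, index=False)


def read_maps(path) -> list:
    """Rebuild SpheriCellMaps from a map CSV."""
    df = pd.read_csv(path)
    grid = DEFAULT_GRID
    maps = []
    for cell_id, sub in df.groupby("cell_id", sort=False):
        channels = list(dict.fromkeys(sub["channel"]))
        n_c = len(channels)
        intensities = np.full((n_c, grid.n_shells, grid.n_sectors), np.nan)
        volumes = np.zeros((grid.n_shells, grid.n_sectors))
        counts = np.zeros((grid.n_shells, grid.n_sectors), dtype=int)
        sector_idx = {name: k for k, name in enumerate(grid.sector_names)}
        for _, row in sub.iterrows():
            ci = channels.index(row["channel"])
            mu = int(row["shell"]) - 1
            nu = sector_idx[row["sector"]]
            intensities[ci, mu, nu] = row["mean_intensity"]
            volumes[mu, nu] = row["volume_um3"]
            counts[mu, nu] = int(row["voxel_count"])
        first = sub.iloc[0]
        frame = MitoticFrame(
            phase=first["phase"],
            center=np.array([first["center_z"], first["center_y"], first["center_x"]]),
            axis=np.array([first["axis_z"], first["axis_y"], first["axis_x"]]),
            sphere_radius=float(first["sphere_radius_um"]),
        )
        maps.append(
            SpheriCellMap(
                intensities=intensities, volumes=volumes, voxel_counts=counts,
                frame=frame, channel_names=channels, cell_id=str(cell_id),
                grid=grid,
            )
        )
    return maps


def measures_to_frame(measures: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": m.cell_id, "species": m.species, "phase": m.phase,
                "c": m.c, "a": m.a, "r": m.r, "phi": m.phi,
            }
            for m in measures
        ]
    )


def read_measures(path) -> list:
    df = pd.read_csv(path)
    return [
        CellMeasures(
            cell_id=row.cell_id, species=row.species, phase=row.phase,
            c=row.c, a=row.a, r=row.r, phi=row.phi,
        )
        for row in df.itertuples()
    ]


def dataset_to_frames(dataset: NormalizedDataset) -> tuple:
    """A NormalizedDataset as (roi_table, totals_table) DataFrames."""
    grid = DEFAULT_GRID
    n, s, l = dataset.roi.shape
    shells = np.repeat(np.arange(1, grid.n_shells + 1), grid.n_sectors)
    sectors = list(grid.sector_names) * grid.n_shells
    rows = []
    for c in range(n):
        for i, sp in enumerate(dataset.species.names):
            for k in range(l):
                rows.append({
                    "cell_id": dataset.cell_ids[c],
                    "phase": dataset.phases[c],
                    "species": sp,
                    "shell": int(shells[k]),
                    "sector": sectors[k],
                    "intensity": dataset.roi[c, i, k],
                })
    roi_df = pd.DataFrame(rows)
    totals_df = pd.DataFrame(
        {
            "cell_id": np.repeat(dataset.cell_ids, s),
            "phase": np.repeat(dataset.phases, s),
            "species": list(dataset.species.names) * n,
            "total": dataset.totals.ravel(),
        }
    )
    return roi_df, totals_df


def write_dataset(dataset: NormalizedDataset, roi_path, totals_path) -> None:
    roi_df, totals_df = dataset_to_frames(dataset)
    roi_df.to_csv(roi_path, index=False)
    totals_df.to_csv(totals_path, index=False)


def read_dataset(roi_path, totals_path=None, normalized: bool = True):
    """Read a ROI table (and totals) back into a NormalizedDataset.

    With ``normalized=False`` the table is treated as raw intensities and
    passed through :func:`sphericell.model.normalize_dataset`.
    """
    grid = DEFAULT_GRID
    df = pd.read_csv(roi_path)
    cell_ids = list(dict.fromkeys(df["cell_id"]))
    species_names = tuple(dict.fromkeys(df["species"]))
    species = SpeciesSet(species_names)
    sector_idx = {name: k for k, name in enumerate(grid.sector_names)}
    n, s = len(cell_ids), len(species_names)
    roi = np.full((n, s, grid.n_rois), np.nan)
    phases = np.empty(n, dtype=object)
    cell_pos = {cid: k for k, cid in enumerate(cell_ids)}
    sp_pos = {sp: k for k, sp in enumerate(species_names)}
    for row in df.itertuples():
        c = cell_pos[row.cell_id]
        i = sp_pos[row.species]
        k = (int(row.shell) - 1) * grid.n_sectors + sector_idx[row.sector]
        roi[c, i, k] = row.intensity
        phases[c] = row.phase
    if np.any(np.isnan(roi)):
        raise ValueError("ROI table is incomplete")
    if not normalized:
        return normalize_dataset(roi, phases, species, cell_ids=cell_ids)
    if totals_path is None:
        raise ValueError("normalized tables require the totals CSV")
    tdf = pd.read_csv(totals_path)
    totals = np.empty((n, s))
    for row in tdf.itertuples():
        totals[cell_pos[row.cell_id], sp_pos[row.species]] = row.total
    return NormalizedDataset(
        species=species, phases=phases.astype(str), roi=roi, totals=totals,
        medians=np.ones(s), volumes=grid.roi_volume_fractions().ravel(),
        cell_ids=cell_ids,
    )


def write_fit_json(fit, path) -> None:
    p = fit.params
    payload = {
        "species": list(p.species.names),
        "interactions": [list(pair) for pair in p.interactions.pairs],
        "provenance": {
            f"{i}-{j}": p.interactions.provenance[(i, j)]
            for i, j in p.interactions.pairs
        },
        "d_meta": p.d_meta.tolist(),
        "d_segr": p.d_segr.tolist(),
        "alpha_meta": p.alpha_meta.tolist(),
        "alpha_segr": p.alpha_segr.tolist(),
        "beta_values": p.beta_values.tolist(),
        "rss": fit.rss,
        "n_starts": fit.n_starts,
        "spread": fit.spread,
        "converged": bool(fit.converged),
        "seed": fit.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_interactions_json(path, species: SpeciesSet):
    """Species/interaction config: ``{"species": [...], "literature_pairs":
    [[name_or_index, name_or_index], ...]}``."""
    from .model import InteractionSet

    cfg = json.loads(Path(path).read_text())
    if "species" in cfg and tuple(cfg["species"]) != species.names:
        raise ValueError("species list in config does not match the dataset")
    pairs = []
    for a, b in cfg.get("literature_pairs", []):
        ia = species.index(a) if isinstance(a, str) else int(a)
        ib = species.index(b) if isinstance(b, str) else int(b)
        pairs.append((ia, ib))
    return InteractionSet(pairs)
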