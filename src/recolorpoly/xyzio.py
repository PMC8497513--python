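"""Trajectory, observable and image file formats.

Trajectories are written as an extended-XYZ dialect chosen for
diffability: per frame, line 1 is the bead count, line 2 a
``key=value`` comment (time, box_side, optional seed), then one line per
bead with ``species x y z state`` where species is ``C`` (chromatin) or
``P`` (protein) and state is the colour code 0=NEUTRAL, 1=K27ME3, 2=UB,
3=K27ME3_UB (-1 for proteins).  Positions are printed with 9 significant
digits; read(write()) is the identity on states exactly and on positions
at the printed precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import Trajectory
from .observables import EnsembleSummary, ObservableSeries
from .states import CHROMATIN, PROTEIN

_SPECIES_CODE = {CHROMATIN: "C", PROTEIN: "P"}
_CODE_SPECIES = {"C": CHROMATIN, "P": PROTEIN}


class TrajectoryParseError(ValueError):
    """Malformed trajectory file; message names the offending frame/line."""


def write_trajectory(traj: Trajectory, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for t, pos, img, states in traj.frames:
            unwrapped = pos + img * traj.box_side
            n = len(pos)
            fh.write(f"{n}\n")
            meta = f"time={t:.9g} box_side={traj.box_side:.9g}"
            if traj.seed is not None:
                meta += f" seed={traj.seed}"
            fh.write(meta + "\n")
            nc = len(states)
            for i in range(n):
                sp = _SPECIES_CODE[int(traj.species[i])]
                st = int(states[i]) if i < nc else -1
                x, y, z = unwrapped[i]
                fh.write(f"{sp} {x:.9g} {y:.9g} {z:.9g} {st}\n")


def read_trajectory(path) -> Trajectory:
    path = Path(path)
    lines = path.read_text().splitlines()
    traj = Trajectory()
    idx = 0
    frame_no = 0
    species = None
    while idx < len(lines):
        if not lines[idx].strip():
            idx += 1
            continue
        try:
            n = int(lines[idx].strip())
        except ValueError as exc:
            raise TrajectoryParseError(
                f"frame {frame_no}: expected bead count at line {idx + 1}"
            ) from exc
        if idx + 1 >= len(lines):
            raise TrajectoryParseError(f"frame {frame_no}: missing comment line")
        meta = dict(
            kv.split("=", 1) for kv in lines[idx + 1].split() if "=" in kv
        )
        if "time" not in meta or "box_side" not in meta:
            raise TrajectoryParseError(
                f"frame {frame_no}: comment line must carry time= and box_side="
            )
        t = float(meta["time"])
        box = float(meta["box_side"])
        if traj.seed is None and "seed" in meta:
            traj.seed = int(meta["seed"])
        pos = np.empty((n, 3))
        states_list = []
        sp = np.empty(n, dtype=np.uint8)
        for k in range(n):
            lineno = idx + 2 + k
            if lineno >= len(lines):
                raise TrajectoryParseError(
                    f"frame {frame_no}: truncated at bead {k} (line {lineno + 1})"
                )
            parts = lines[lineno].split()
            if len(parts) != 5:
                raise TrajectoryParseError(
                    f"frame {frame_no}: line {lineno + 1} has {len(parts)} fields, "
                    "expected 5 (species x y z state)"
                )
            if parts[0] not in _CODE_SPECIES:
                raise TrajectoryParseError(
                    f"frame {frame_no}: unknown species {parts[0]!r} at line {lineno + 1}"
                )
            sp[k] = _CODE_SPECIES[parts[0]]
            pos[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
            st = int(parts[4])
            if parts[0] == "C":
                if st not in (0, 1, 2, 3):
                    raise TrajectoryParseError(
                        f"frame {frame_no}: invalid state code {st} at line {lineno + 1}"
                    )
                states_list.append(st)
        if species is None:
            species = sp
            traj.species = sp
            traj.box_side = box
        elif not np.array_equal(species, sp):
            raise TrajectoryParseError(
                f"frame {frame_no}: species ordering differs from frame 0"
            )
        img = np.floor(pos / box).astype(np.int64)
        wrapped = pos - img * box
        traj.frames.append(
            (t, wrapped, img, np.array(states_list, dtype=np.uint8))
        )
        idx += 2 + n
        frame_no += 1
    if not traj.frames:
        raise TrajectoryParseError("no frames found")
    return traj


OBSERVABLE_COLUMNS = ["time", "rg2", "mean_density", "density_sq", "n_ub"]


def write_observables(series: ObservableSeries, path) -> None:
    """Observables CSV with columns time, rg2, mean_density, density_sq, n_ub."""
    df = pd.DataFrame(
        {
            "time": series.times,
            "rg2": series.rg2,
            "mean_density": series.mean_density,
            "density_sq": series.density_sq,
            "n_ub": series.n_ub,
        }
    )
    df.to_csv(path, index=False)


def read_observables(path) -> ObservableSeries:
    df = pd.read_csv(path)
    missing = set(OBSERVABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"observables CSV missing columns: {sorted(missing)}")
    return ObservableSeries(
        times=df["time"].to_numpy(float),
        rg2=df["rg2"].to_numpy(float),
        mean_density=df["mean_density"].to_numpy(float),
        density_sq=df["density_sq"].to_numpy(float),
        n_ub=df["n_ub"].to_numpy(np.int64),
    )


def write_ensemble(summary: EnsembleSummary, path) -> None:
    """Ensemble CSV: time plus <name>_mean / <name>_sd column pairs."""
    data = {"time": summary.times}
    for name in summary.mean:
        data[f"{name}_mean"] = summary.mean[name]
        data[f"{name}_sd"] = summary.sd[name]
    pd.DataFrame(data).to_csv(path, index=False)


def write_events(events, path) -> None:
    """Recoloring events CSV: time, n_selected, n_written, cumulative_ub."""
    cum = np.cumsum([e.n_written for e in events]) if events else []
    pd.DataFrame(
        {
            "time": [e.time for e in events],
            "n_selected": [e.n_selected for e in events],
            "n_written": [e.n_written for e in events],
            "cumulative_ub_writes": cum,
        }
    ).to_csv(path, index=False)


def write_image(img, path) -> None:
    """Write a channel image as 16-bit grayscale TIFF (or PNG by suffix)."""
    import tifffile

    path = Path(path)
    arr = np.clip(np.round(img.intensities), 0, 65535).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, arr)


def read_image(path, pixel_size: float = 1.0, label: str = ""):
    from .imaging import ChannelImage

    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    return ChannelImage(np.asarray(arr, dtype=float), pixel_size=pixel_size, label=label)


def write_mask(mask: np.ndarray, path) -> None:
    """Write a boolean mask as 8-bit TIFF/PNG with values 0/255."""
    import tifffile

    path = Path(path)
    arr = np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, arr)


def read_mask(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    return np.asarray(arr) > 0
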