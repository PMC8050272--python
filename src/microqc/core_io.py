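"""Image-stack and localisation-table IO plus stack utilities.

Coordinate convention used throughout the toolkit: pixel indices are 0-based,
tiles and bounding boxes are half-open intervals, and the physical position of
pixel ``(row, col)`` is its centre, ``x_nm = (col + 0.5) * pixel_size_nm`` and
``y_nm = (row + 0.5) * pixel_size_nm``.  This keeps simulator → renderer →
extraction round trips free of half-pixel bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack",
    "PairedDataset",
    "LocalisationTable",
    "read_image_stack",
    "write_image_stack",
    "bin_frames",
    "split_tiles",
    "assemble_tiles",
    "pair_datasets",
    "read_localisations",
    "write_localisations",
]

#: ThunderSTORM-style canonical column names, in write order.
THUNDERSTORM_COLUMNS = ("frame", "x [nm]", "y [nm]", "intensity [photon]", "sigma [nm]")

#: Accepted spellings for each mandatory/optional localisation column.
_COLUMN_ALIASES = {
    "frame": ("frame", "frame_idx", '"frame"'),
    "x [nm]": ("x [nm]", "x[nm]", "x_nm", "x", "x (nm)"),
    "y [nm]": ("y [nm]", "y[nm]", "y_nm", "y", "y (nm)"),
    "intensity [photon]": (
        "intensity [photon]",
        "intensity[photon]",
        "intensity",
        "photons",
        "photon",
    ),
    "sigma [nm]": ("sigma [nm]", "sigma[nm]", "sigma_nm", "sigma"),
}


@dataclass
class ImageStack:
    """An ordered sequence of equally shaped 2D frames with optional pixel size."""

    frames: np.ndarray  # shape (n, H, W)
    pixel_size_nm: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (n, H, W); got shape {self.frames.shape}")
        if self.frames.shape[0] < 1:
            raise ValueError("a stack needs at least one frame")
        if self.pixel_size_nm is not None and self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial (H, W) shape of every frame."""
        return self.frames.shape[1:]

    @property
    def dtype(self) -> np.dtype:
        return self.frames.dtype


@dataclass
class PairedDataset:
    """Source/target pairs of identical spatial shape, keyed by name."""

    pairs: list[tuple[np.ndarray, np.ndarray, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [name for _, _, name in self.pairs]
        if len(set(names)) != len(names):
            raise ValueError("pair names must be unique")
        for src, tgt, name in self.pairs:
            if np.shape(src) != np.shape(tgt):
                raise ValueError(f"pair {name!r}: source shape {np.shape(src)} != target {np.shape(tgt)}")

    def __len__(self) -> int:
        return len(self.pairs)


class LocalisationTable:
    """Per-emitter records: frame (1-based), x/y in nm, photons, optional sigma.

    Backed by a :class:`pandas.DataFrame` with the canonical ThunderSTORM column
    names; unknown extra columns are carried along untouched.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in ("frame", "x [nm]", "y [nm]") if c not in df.columns]
        if missing:
            raise ValueError(f"localisation table lacks mandatory columns: {missing}")
        df = df.reset_index(drop=True)
        if len(df):
            if (df["frame"] < 1).any():
                raise ValueError("frame indices are 1-based and must be >= 1")
            if not np.isfinite(df[["x [nm]", "y [nm]"]].to_numpy(float)).all():
                raise ValueError("coordinates must be finite")
            if "intensity [photon]" in df.columns and (df["intensity [photon]"] < 0).any():
                raise ValueError("photon counts must be non-negative")
        self.df = df

    @classmethod
    def from_arrays(
        cls,
        frame: Sequence[int],
        x_nm: Sequence[float],
        y_nm: Sequence[float],
        photons: Sequence[float] | None = None,
        sigma_nm: Sequence[float] | None = None,
    ) -> "LocalisationTable":
        data: dict[str, np.ndarray] = {
            "frame": np.asarray(frame, dtype=int),
            "x [nm]": np.asarray(x_nm, dtype=float),
            "y [nm]": np.asarray(y_nm, dtype=float),
        }
        if photons is not None:
            data["intensity [photon]"] = np.asarray(photons, dtype=float)
        if sigma_nm is not None:
            data["sigma [nm]"] = np.asarray(sigma_nm, dtype=float)
        return cls(pd.DataFrame(data))

    @classmethod
    def empty(cls) -> "LocalisationTable":
        return cls.from_arrays([], [], [], [], [])

    def __len__(self) -> int:
        return len(self.df)

    @property
    def frame(self) -> np.ndarray:
        return self.df["frame"].to_numpy(int)

    @property
    def x_nm(self) -> np.ndarray:
        return self.df["x [nm]"].to_numpy(float)

    @property
    def y_nm(self) -> np.ndarray:
        return self.df["y [nm]"].to_numpy(float)

    @property
    def photons(self) -> np.ndarray:
        if "intensity [photon]" in self.df.columns:
            return self.df["intensity [photon]"].to_numpy(float)
        return np.ones(len(self.df))

    @property
    def sigma_nm(self) -> np.ndarray | None:
        if "sigma [nm]" in self.df.columns:
            return self.df["sigma [nm]"].to_numpy(float)
        return None


# ---------------------------------------------------------------------------
# TIFF stacks


def read_image_stack(path: str | Path, pixel_size_nm: float | None = None) -> ImageStack:
    """Read a single- or multi-page TIFF into an :class:`ImageStack`.

    Frames keep the file's page order and dtype; a single-page file yields a
    one-frame stack.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # tifffile raises assorted types for bad payloads
        raise ValueError(f"{path} is not a readable TIFF image: {exc}") from exc
    return ImageStack(frames=arr, pixel_size_nm=pixel_size_nm)


def write_image_stack(stack: ImageStack | np.ndarray, path: str | Path) -> None:
    """Write a stack as a multi-page TIFF, losslessly for integer and float32 data."""
    if not isinstance(stack, ImageStack):
        stack = ImageStack(frames=stack)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.frames, photometric="minisblack")


# ---------------------------------------------------------------------------
# Stack utilities


def bin_frames(stack: ImageStack, group_size: int) -> ImageStack:
    """Sum consecutive groups of ``group_size`` frames (grouped z-project, sum).

    Accumulation is in float32 regardless of input dtype; an incomplete trailing
    group is dropped, so the output has ``floor(n / group_size)`` frames.
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    n = stack.n_frames
    n_out = n // group_size
    if n_out == 0:
        raise ValueError(f"stack of {n} frames has no complete group of {group_size}")
    frames = stack.frames[: n_out * group_size].astype(np.float32)
    binned = frames.reshape(n_out, group_size, *stack.shape).sum(axis=1, dtype=np.float32)
    return ImageStack(frames=binned, pixel_size_nm=stack.pixel_size_nm)


def split_tiles(stack: ImageStack, tile_height: int, tile_width: int) -> list[ImageStack]:
    """Split each frame into non-overlapping tiles, keeping the full depth axis.

    Tiles are returned in row-major order; tile dimensions must divide the frame
    dimensions exactly.
    """
    h, w = stack.shape
    if tile_height < 1 or tile_width < 1:
        raise ValueError("tile dimensions must be positive")
    if h % tile_height or w % tile_width:
        raise ValueError(
            f"tile {tile_height}x{tile_width} does not evenly divide frame {h}x{w}"
        )
    tiles = []
    for r0 in range(0, h, tile_height):
        for c0 in range(0, w, tile_width):
            tiles.append(
                ImageStack(
                    frames=stack.frames[:, r0 : r0 + tile_height, c0 : c0 + tile_width].copy(),
                    pixel_size_nm=stack.pixel_size_nm,
                )
            )
    return tiles


def assemble_tiles(tiles: Sequence[ImageStack], n_rows: int, n_cols: int) -> ImageStack:
    """Inverse of :func:`split_tiles` for a row-major tile sequence."""
    if len(tiles) != n_rows * n_cols:
        raise ValueError("tile count does not match the requested grid")
    rows = [
        np.concatenate([t.frames for t in tiles[r * n_cols : (r + 1) * n_cols]], axis=2)
        for r in range(n_rows)
    ]
    return ImageStack(frames=np.concatenate(rows, axis=1), pixel_size_nm=tiles[0].pixel_size_nm)


def pair_datasets(
    source_dir: str | Path,
    target_dir: str | Path,
    by_order: bool = False,
) -> PairedDataset:
    """Pair source/target image files from two directories.

    Default pairing is by identical filename; files lacking a partner are
    reported with a warning and excluded.  ``by_order`` pairs the sorted file
    lists positionally instead (fragile; off by default).
    """
    source_dir, target_dir = Path(source_dir), Path(target_dir)
    src_files = sorted(p for p in source_dir.iterdir() if p.is_file())
    tgt_files = sorted(p for p in target_dir.iterdir() if p.is_file())
    if by_order:
        matched = list(zip(src_files, tgt_files))
        for p in src_files[len(matched) :] + tgt_files[len(matched) :]:
            warnings.warn(f"unpaired file (order mode): {p}", stacklevel=2)
    else:
        tgt_by_name = {p.name: p for p in tgt_files}
        matched = []
        for p in src_files:
            if p.name in tgt_by_name:
                matched.append((p, tgt_by_name.pop(p.name)))
            else:
                warnings.warn(f"source file without target: {p.name}", stacklevel=2)
        for name in tgt_by_name:
            warnings.warn(f"target file without source: {name}", stacklevel=2)
    if not matched:
        raise ValueError(f"no matching pairs between {source_dir} and {target_dir}")
    pairs = []
    for sp, tp in matched:
        src = tifffile.imread(sp)
        tgt = tifffile.imread(tp)
        if src.shape != tgt.shape:
            raise ValueError(
                f"pair {sp.name!r}: source shape {src.shape} != target shape {tgt.shape}"
            )
        pairs.append((src, tgt, sp.name))
    return PairedDataset(pairs=pairs)


# ---------------------------------------------------------------------------
# Localisation tables


def _canonicalise_columns(df: pd.DataFrame) -> pd.DataFrame:
    rename: dict[str, str] = {}
    taken: set[str] = set()
    for canonical, aliases in _COLUMN_ALIASES.items():
        for col in df.columns:
            if col.strip().strip('"').lower() in aliases and canonical not in taken:
                rename[col] = canonical
                taken.add(canonical)
                break
    return df.rename(columns=rename)


def read_localisations(path: str | Path, dialect: str = "thunderstorm_csv") -> LocalisationTable:
    """Read a ThunderSTORM-style localisation CSV.

    Both ``"x [nm]"`` and bare ``"x"`` header spellings are accepted; unknown
    extra columns are preserved verbatim.
    """
    if dialect != "thunderstorm_csv":
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path)
    df = _canonicalise_columns(df)
    missing = [c for c in ("frame", "x [nm]", "y [nm]") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing} (found {list(df.columns)})")
    return LocalisationTable(df)


def write_localisations(table: LocalisationTable, path: str | Path) -> None:
    """Write a localisation table as ThunderSTORM-style CSV (canonical headers first)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    known = [c for c in THUNDERSTORM_COLUMNS if c in table.df.columns]
    extra = [c for c in table.df.columns if c not in known]
    table.df[known + extra].to_csv(path, index=False)
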