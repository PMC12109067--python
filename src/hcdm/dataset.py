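"""Synthetic moving-object frame-pair dataset.

Each sample is a pair of consecutive 32x32x3 8-bit frames in which a small
4-connected object translates by exactly one pixel step in one of eight
compass directions.  Background and object pixels follow one of three color
regimes -- ``dark`` (all zeros), ``constant`` (one shared random intensity
1..255 in all channels) or ``random`` (i.i.d. uniform 1..255 per pixel and
channel) -- and the eight valid background/object regime combinations (the
3x3 grid minus the invisible dark-on-dark case) define the eight dataset
groups.  Optional salt-and-pepper or Gaussian corruption models sensor noise.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "MotionDirection",
    "ColorRegime",
    "NoiseSpec",
    "FramePair",
    "GROUPS",
    "OBJECT_SIZES",
    "generate_object",
    "render_pair",
    "add_salt_pepper",
    "add_gaussian",
    "build_group",
    "build_mixed",
    "save_pairs",
    "load_pairs",
]

#: Object pixel counts used throughout the experiments.
OBJECT_SIZES: tuple[int, ...] = (1, 2, 4, 8, 16, 32, 64, 128)

DEFAULT_SHAPE = (32, 32)


class MotionDirection(enum.IntEnum):
    """The eight one-pixel displacement directions, coded 1..8.

    Offsets are (dy, dx) in image coordinates (row grows downward), so
    ``N`` is (-1, 0).  The code <-> offset bijection is fixed.
    """

    E = 1
    NE = 2
    N = 3
    NW = 4
    W = 5
    SW = 6
    S = 7
    SE = 8

    @property
    def offset(self) -> tuple[int, int]:
        return _OFFSETS[self.value]


_OFFSETS: dict[int, tuple[int, int]] = {
    1: (0, 1),
    2: (-1, 1),
    3: (-1, 0),
    4: (-1, -1),
    5: (0, -1),
    6: (1, -1),
    7: (1, 0),
    8: (1, 1),
}


@dataclass(frozen=True)
class ColorRegime:
    """Pixel-intensity regime for either the background or the object.

    ``dark`` fills with 0; ``constant`` fills every assigned pixel and channel
    with one stored scalar in 1..255; ``random`` draws each pixel/channel
    independently uniform on the integers 1..255.
    """

    mode: str  # dark | constant | random
    value: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("dark", "constant", "random"):
            raise ValueError(f"unknown color mode {self.mode!r}")
        if self.mode == "constant":
            if self.value is None or not (1 <= int(self.value) <= 255):
                raise ValueError("constant regime requires value in 1..255")
        elif self.value is not None:
            raise ValueError(f"{self.mode!r} regime takes no value")

    @staticmethod
    def sample(mode: str, rng: np.random.Generator) -> "ColorRegime":
        """Instantiate a regime, drawing the scalar for ``constant`` mode."""
        if mode == "constant":
            return ColorRegime("constant", int(rng.integers(1, 256)))
        return ColorRegime(mode)

    def fill(self, shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
        """A full frame (H, W, 3) uint8 of this regime."""
        h, w = shape
        if self.mode == "dark":
            return np.zeros((h, w, 3), dtype=np.uint8)
        if self.mode == "constant":
            return np.full((h, w, 3), self.value, dtype=np.uint8)
        return rng.integers(1, 256, size=(h, w, 3), dtype=np.uint8)

    def paint(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Colors for ``n`` object pixels, shape (n, 3) uint8."""
        if self.mode == "dark":
            return np.zeros((n, 3), dtype=np.uint8)
        if self.mode == "constant":
            return np.full((n, 3), self.value, dtype=np.uint8)
        return rng.integers(1, 256, size=(n, 3), dtype=np.uint8)


@dataclass(frozen=True)
class NoiseSpec:
    """Test-time corruption: ``salt_pepper`` (fraction ``rate`` of pixel
    positions set to pure black/white), ``gaussian`` (zero-mean additive,
    ``std``), or ``none``."""

    kind: str = "none"  # none | salt_pepper | gaussian
    rate: float | None = None
    std: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "salt_pepper", "gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.kind == "salt_pepper":
            if self.rate is None or not (0.0 <= self.rate <= 1.0):
                raise ValueError("salt_pepper requires rate in [0, 1]")
        if self.kind == "gaussian":
            if self.std is None or self.std < 0:
                raise ValueError("gaussian requires std >= 0")

    def apply(self, image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none":
            return image.copy()
        if self.kind == "salt_pepper":
            return add_salt_pepper(image, self.rate, rng)
        return add_gaussian(image, self.std, rng)

    @property
    def param(self) -> float:
        if self.kind == "salt_pepper":
            return float(self.rate)
        if self.kind == "gaussian":
            return float(self.std)
        return 0.0


@dataclass
class FramePair:
    """Two consecutive frames with the motion label and generation metadata."""

    frame_t: np.ndarray
    frame_t1: np.ndarray
    label: MotionDirection
    meta: dict = field(default_factory=dict)

    def with_noise(self, spec: NoiseSpec, rng: np.random.Generator) -> "FramePair":
        """A copy with ``spec`` applied independently to both frames."""
        return FramePair(
            frame_t=spec.apply(self.frame_t, rng),
            frame_t1=spec.apply(self.frame_t1, rng),
            label=self.label,
            meta={**self.meta, "noise_kind": spec.kind, "noise_param": spec.param},
        )


#: The eight valid (background, object) regime pairs.  dark-dark is excluded:
#: a dark object on a dark background carries no signal.
GROUPS: tuple[tuple[str, str], ...] = (
    ("dark", "constant"),
    ("dark", "random"),
    ("constant", "dark"),
    ("constant", "constant"),
    ("constant", "random"),
    ("random", "dark"),
    ("random", "constant"),
    ("random", "random"),
)


def group_id(background: str, obj: str) -> str:
    if (background, obj) not in GROUPS:
        raise ValueError(f"invalid group {background}-{obj}")
    return f"{background}-{obj}"


def parse_group(gid: str) -> tuple[str, str]:
    try:
        background, obj = gid.split("-")
    except ValueError:
        raise ValueError(f"malformed group id {gid!r}") from None
    if (background, obj) not in GROUPS:
        raise ValueError(f"invalid group {gid!r}")
    return background, obj


# Offsets of the 4-neighborhood used for connected growth.
_N4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
_N8 = _N4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


def generate_object(
    size: int,
    rng: np.random.Generator,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    connectivity: int = 4,
) -> np.ndarray:
    """Grow a random connected pixel set of exactly ``size`` cells.

    Growth starts from a single seed cell and repeatedly attaches a uniformly
    random frontier cell (a cell adjacent to the current set), producing
    random but connected shapes.  Coordinates are returned normalized to the
    bounding-box origin, as an (size, 2) int array of (row, col).
    """
    h, w = shape
    if size < 1:
        raise ValueError("object size must be >= 1")
    if size > h * w:
        raise ValueError(f"object size {size} exceeds frame capacity {h * w}")
    neigh = _N4 if connectivity == 4 else _N8

    cells: set[tuple[int, int]] = {(0, 0)}
    frontier: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = {(0, 0)}

    def push_neighbors(cell: tuple[int, int]) -> None:
        for dy, dx in neigh:
            cand = (cell[0] + dy, cell[1] + dx)
            if cand not in seen:
                seen.add(cand)
                frontier.append(cand)

    push_neighbors((0, 0))
    while len(cells) < size:
        idx = int(rng.integers(len(frontier)))
        cell = frontier.pop(idx)
        cells.add(cell)
        push_neighbors(cell)

    arr = np.array(sorted(cells), dtype=np.int64)
    arr -= arr.min(axis=0)  # normalize to bounding-box origin
    if arr[:, 0].max() >= h or arr[:, 1].max() >= w:
        # Extremely elongated draws can exceed the frame; regrow.
        return generate_object(size, rng, shape, connectivity)
    return arr


def _place(
    mask: np.ndarray,
    direction: MotionDirection,
    shape: tuple[int, int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Absolute placement such that the mask and its translate both fit."""
    h, w = shape
    dy, dx = direction.offset
    mh = int(mask[:, 0].max())
    mw = int(mask[:, 1].max())
    r_lo, r_hi = max(0, -dy), h - 1 - mh - max(0, dy)
    c_lo, c_hi = max(0, -dx), w - 1 - mw - max(0, dx)
    if r_hi < r_lo or c_hi < c_lo:
        raise ValueError("object too large to move within the frame")
    r0 = int(rng.integers(r_lo, r_hi + 1))
    c0 = int(rng.integers(c_lo, c_hi + 1))
    return mask + np.array([r0, c0])


def render_pair(
    object_mask: np.ndarray,
    direction: MotionDirection,
    background: ColorRegime,
    obj: ColorRegime,
    rng: np.random.Generator,
    shape: tuple[int, int] = DEFAULT_SHAPE,
) -> FramePair:
    """Render the two frames of one motion sample.

    The object keeps its exact pixel colors between frames and translates by
    the direction's offset.  ``random`` backgrounds are regenerated
    independently for each frame (the background flickers, so object motion
    is the only temporally reliable cue); ``dark``/``constant`` backgrounds
    are shared between frames.
    """
    if background.mode == "dark" and obj.mode == "dark":
        raise ValueError("dark background with dark object renders an invisible object")
    placed = _place(object_mask, direction, shape, rng)
    dy, dx = direction.offset
    moved = placed + np.array([dy, dx])

    colors = obj.paint(len(placed), rng)
    bg_t = background.fill(shape, rng)
    if background.mode == "random":
        bg_t1 = background.fill(shape, rng)
    else:
        bg_t1 = bg_t.copy()

    frame_t = bg_t
    frame_t[placed[:, 0], placed[:, 1]] = colors
    frame_t1 = bg_t1
    frame_t1[moved[:, 0], moved[:, 1]] = colors

    meta = {
        "object_size": int(len(object_mask)),
        "background": background,
        "object": obj,
        "object_mask_t": placed,
        "noise_kind": "none",
        "noise_param": 0.0,
    }
    return FramePair(frame_t=frame_t, frame_t1=frame_t1, label=direction, meta=meta)


def add_salt_pepper(image: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Corrupt exactly round(rate*H*W) pixel positions with pure black/white.

    Positions are sampled without replacement; each corrupted position is set
    in all three channels to 255 with probability p_salt (drawn once per image
    uniformly on (0,1)) and to 0 otherwise.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError("salt-and-pepper rate must lie in [0, 1]")
    h, w = image.shape[:2]
    n = int(np.rint(rate * h * w))
    out = image.copy()
    if n == 0:
        return out
    flat = rng.choice(h * w, size=n, replace=False)
    p_salt = rng.uniform()
    salt = rng.uniform(size=n) < p_salt
    vals = np.where(salt, 255, 0).astype(np.uint8)
    out.reshape(h * w, -1)[flat] = vals[:, None]
    return out


def add_gaussian(image: np.ndarray, std: float, rng: np.random.Generator) -> np.ndarray:
    """Add zero-mean Gaussian noise per pixel and channel, round, clip to 0..255."""
    if std < 0:
        raise ValueError("gaussian std must be >= 0")
    if std == 0:
        return image.copy()
    noisy = image.astype(np.float64) + rng.normal(0.0, std, size=image.shape)
    return np.clip(np.rint(noisy), 0, 255).astype(np.uint8)


def _pair_stream(master_seed: int, start: int = 0):
    """Deterministic per-pair substreams from one master seed (counter-based)."""
    i = start
    while True:
        yield np.random.default_rng(np.random.SeedSequence([int(master_seed), i]))
        i += 1


def build_group(
    group: str,
    n_pairs: int,
    seed: int,
    sizes: Sequence[int] = OBJECT_SIZES,
    noise: NoiseSpec = NoiseSpec(),
    shape: tuple[int, int] = DEFAULT_SHAPE,
) -> list[FramePair]:
    """Generate ``n_pairs`` samples of one background-object group.

    Direction labels are balanced (``n_pairs`` divisible by 8 gives exact
    balance); object sizes are drawn uniformly from ``sizes``.  Identical
    seeds yield identical datasets.
    """
    bg_mode, obj_mode = parse_group(group)
    directions = [MotionDirection(1 + (i % 8)) for i in range(n_pairs)]
    pairs: list[FramePair] = []
    for direction, rng in zip(directions, _pair_stream(seed)):
        size = int(sizes[int(rng.integers(len(sizes)))])
        mask = generate_object(size, rng, shape)
        background = ColorRegime.sample(bg_mode, rng)
        obj = ColorRegime.sample(obj_mode, rng)
        if background.mode == "constant" and obj.mode == "constant":
            while obj.value == background.value:
                obj = ColorRegime.sample(obj_mode, rng)
        pair = render_pair(mask, direction, background, obj, rng, shape)
        pair.meta["group"] = group
        if noise.kind != "none":
            pair = pair.with_noise(noise, rng)
            pair.meta["group"] = group
        pairs.append(pair)
    return pairs


def build_mixed(
    n_pairs: int,
    seed: int,
    sizes: Sequence[int] = OBJECT_SIZES,
    noise: NoiseSpec = NoiseSpec(),
    shape: tuple[int, int] = DEFAULT_SHAPE,
    groups: Sequence[str] | None = None,
) -> list[FramePair]:
    """An evenly mixed dataset drawing ``n_pairs`` samples across all groups.

    Samples are interleaved group-by-group so any prefix is close to balanced
    in both group and direction.
    """
    gids = list(groups) if groups is not None else [f"{b}-{o}" for b, o in GROUPS]
    per = -(-n_pairs // len(gids))  # ceil
    chunks = [
        build_group(g, per, seed=int(np.random.SeedSequence([seed, 977, k]).generate_state(1)[0] % (2**31)),
                    sizes=sizes, noise=noise, shape=shape)
        for k, g in enumerate(gids)
    ]
    mixed: list[FramePair] = []
    for i in range(per):
        for chunk in chunks:
            mixed.append(chunk[i])
    return mixed[:n_pairs]


# ---------------------------------------------------------------------------
# Serialization: paired PNGs + CSV manifest, or a single NPZ archive.
# ---------------------------------------------------------------------------

_MANIFEST_COLS = [
    "id", "direction_code", "object_size", "background_mode", "object_mode",
    "noise_kind", "noise_param", "seed",
]


def save_pairs(pairs: Iterable[FramePair], out_dir: str | Path, fmt: str = "npz") -> Path:
    """Write a dataset to ``out_dir`` as PNG pairs + manifest.csv or one NPZ."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pairs = list(pairs)
    rows = []
    for i, p in enumerate(pairs):
        bg = p.meta.get("background")
        ob = p.meta.get("object")
        rows.append({
            "id": i,
            "direction_code": int(p.label),
            "object_size": p.meta.get("object_size", -1),
            "background_mode": bg.mode if bg is not None else "unknown",
            "object_mode": ob.mode if ob is not None else "unknown",
            "noise_kind": p.meta.get("noise_kind", "none"),
            "noise_param": p.meta.get("noise_param", 0.0),
            "seed": p.meta.get("seed", -1),
        })
    manifest = pd.DataFrame(rows, columns=_MANIFEST_COLS)
    if fmt == "png":
        for i, p in enumerate(pairs):
            Image.fromarray(p.frame_t).save(out / f"{i:06d}_t.png")
            Image.fromarray(p.frame_t1).save(out / f"{i:06d}_t1.png")
        manifest.to_csv(out / "manifest.csv", index=False)
        return out
    if fmt == "npz":
        frames_t = np.stack([p.frame_t for p in pairs])
        frames_t1 = np.stack([p.frame_t1 for p in pairs])
        labels = np.array([int(p.label) for p in pairs], dtype=np.int64)
        path = out / "dataset.npz"
        np.savez_compressed(
            path,
            frames_t=frames_t,
            frames_t1=frames_t1,
            labels=labels,
            manifest=np.frombuffer(
                manifest.to_json(orient="records").encode(), dtype=np.uint8
            ),
        )
        return path
    raise ValueError(f"unknown format {fmt!r}")


def load_pairs(path: str | Path) -> list[FramePair]:
    """Reload a dataset written by :func:`save_pairs` (both formats)."""
    path = Path(path)
    if path.is_dir() and (path / "dataset.npz").exists():
        path = path / "dataset.npz"
    if path.suffix == ".npz":
        with np.load(path) as data:
            frames_t = data["frames_t"]
            frames_t1 = data["frames_t1"]
            labels = data["labels"]
            manifest = json.loads(bytes(data["manifest"]).decode())
        pairs = []
        for i in range(len(labels)):
            meta = dict(manifest[i]) if i < len(manifest) else {}
            pairs.append(FramePair(frames_t[i], frames_t1[i],
                                   MotionDirection(int(labels[i])), meta))
        return pairs
    # PNG directory
    manifest = pd.read_csv(path / "manifest.csv")
    pairs = []
    for _, row in manifest.iterrows():
        i = int(row["id"])
        ft = np.asarray(Image.open(path / f"{i:06d}_t.png"))
        ft1 = np.asarray(Image.open(path / f"{i:06d}_t1.png"))
        pairs.append(FramePair(ft, ft1, MotionDirection(int(row["direction_code"])),
                               dict(row)))
    return pairs
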