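"""Bilayer thickness and local-thinning analysis from trajectory frames.

Membrane-embedded rhomboid pseudo-proteases locally deform the bilayer; the
observable is a 2D map of time-averaged inter-leaflet distance on an x-y
grid.  This module ingests trajectory frames (multi-MODEL PDB or a plain
XYZ-like per-frame point list with leaflet tags), assigns leaflets where
tags are missing, bins one reference point per lipid into a grid, averages
the per-frame upper-minus-lower z distance over a converged trailing window
of the trajectory, and summarizes local thinning (bulk thickness minus the
map minimum).  Maps from two conditions can be differenced bin-by-bin.

No physics is simulated here: frames are analyzed as given.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BilayerFrame",
    "ThicknessMap",
    "ThinningSummary",
    "DifferenceResult",
    "assign_leaflets",
    "thickness_map",
    "thinning_summary",
    "difference_map",
    "write_xyz_frames",
    "read_xyz_frames",
    "write_pdb_frames",
    "read_pdb_frames",
]

UPPER, LOWER, UNASSIGNED = "upper", "lower", "unassigned"


@dataclass
class BilayerFrame:
    """One trajectory snapshot: one reference point per lipid."""

    index: int
    xyz: np.ndarray                     # (n, 3) float, Å
    leaflet: np.ndarray                 # (n,) str in {upper, lower, unassigned}
    lipid_id: np.ndarray | None = None  # (n,) int
    time_ns: float | None = None
    box_xy: tuple[float, float] | None = None  # periodic extents, Å

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must be an (n, 3) array")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"frame {self.index}: non-finite coordinates")
        self.leaflet = np.asarray(self.leaflet, dtype="U10")
        if self.leaflet.shape[0] != self.xyz.shape[0]:
            raise ValueError("leaflet tags and coordinates disagree in length")
        if self.lipid_id is None:
            self.lipid_id = np.arange(self.xyz.shape[0])

    @property
    def n_points(self) -> int:
        return self.xyz.shape[0]


def assign_leaflets(frame: BilayerFrame) -> BilayerFrame:
    """Tag untagged points by a median-z split; existing tags are preserved.

    Points strictly above the frame's median z become ``upper``, strictly
    below become ``lower``; a point exactly at the median is assigned
    ``lower`` with a warning.  A frame whose points all land on one side
    (degenerate, e.g. all-equal z) raises ``ValueError``.
    """
    if frame.n_points < 4:
        raise ValueError("need at least 4 points to assign leaflets")
    tags = frame.leaflet.copy()
    todo = tags == UNASSIGNED
    if todo.any():
        med = float(np.median(frame.xyz[:, 2]))
        z = frame.xyz[todo, 2]
        at_median = z == med
        if at_median.any():
            warnings.warn(
                f"frame {frame.index}: {int(at_median.sum())} point(s) exactly at the "
                "median z assigned to the lower leaflet",
                stacklevel=2,
            )
        tags[todo] = np.where(z > med, UPPER, LOWER)
    if not ((tags == UPPER).any() and (tags == LOWER).any()):
        raise ValueError(f"frame {frame.index}: one-sided frame, cannot form two leaflets")
    return BilayerFrame(
        index=frame.index, xyz=frame.xyz, leaflet=tags, lipid_id=frame.lipid_id,
        time_ns=frame.time_ns, box_xy=frame.box_xy,
    )


@dataclass
class ThicknessMap:
    """Time-averaged inter-leaflet distance on an x-y grid.

    ``mean`` holds the per-bin average over frames in which both leaflets
    were represented in that bin; bins never populated are NaN (empty), and
    ``count`` records the number of contributing frames per bin.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    mean: np.ndarray    # (nx, ny); NaN where empty
    count: np.ndarray   # (nx, ny) frames contributing
    frames_used: int
    window: tuple[int, int]  # [start, end) frame indices of the averaging window

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    @property
    def populated(self) -> np.ndarray:
        return self.count > 0

    def to_tsv(self) -> str:
        """Matrix TSV: first row/column are bin centers, NaN marks empty bins."""
        lines = ["\t".join(["x\\y"] + [f"{y:.3f}" for y in self.y_centers])]
        for i, x in enumerate(self.x_centers):
            row = [f"{x:.3f}"] + [
                "NA" if not np.isfinite(v) else f"{v:.4f}" for v in self.mean[i]
            ]
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"


def _window_slice(n_frames: int, window: tuple[float, float]) -> tuple[int, int]:
    lo, hi = window
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError(f"window fractions must satisfy 0 <= start < end <= 1, got {window}")
    start = int(np.floor(lo * n_frames))
    end = int(np.ceil(hi * n_frames))
    return start, end


def thickness_map(
    frames: Sequence[BilayerFrame],
    bin_size: float = 2.0,
    window: tuple[float, float] = (0.6, 1.0),
) -> ThicknessMap:
    """Average inter-leaflet distance per x-y bin over a trailing frame window.

    For each bin and frame the distance is (mean z of upper-leaflet points in
    the bin) − (mean z of lower-leaflet points); the per-bin value averages
    over the frames in which both leaflets are represented there.  ``window``
    selects a fraction range of the frame sequence; the default trailing 40%
    mirrors analysing the final converged stretch of an equilibrated run.
    Frames with untagged points are leaflet-assigned on the fly.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    n = len(frames)
    if n == 0:
        raise ValueError("no frames given")
    start, end = _window_slice(n, window)
    sel = list(frames[start:end])
    if not sel:
        raise ValueError(f"window {window} selects 0 of {n} frames")
    sel = [f if not (f.leaflet == UNASSIGNED).any() else assign_leaflets(f) for f in sel]

    def _edges(lo: float, hi: float) -> np.ndarray:
        n_bins = max(1, int(np.ceil((hi - lo) / bin_size - 1e-12)))
        return lo + bin_size * np.arange(n_bins + 1)

    box = sel[0].box_xy
    if box is not None:
        x_edges, y_edges = _edges(0.0, box[0]), _edges(0.0, box[1])
    else:
        xs = np.concatenate([f.xyz[:, 0] for f in sel])
        ys = np.concatenate([f.xyz[:, 1] for f in sel])
        x_edges = _edges(np.floor(xs.min()), xs.max())
        y_edges = _edges(np.floor(ys.min()), ys.max())
    nx, ny = len(x_edges) - 1, len(y_edges) - 1

    dist_sum = np.zeros((nx, ny))
    dist_cnt = np.zeros((nx, ny), dtype=int)
    for f in sel:
        x, y, z = f.xyz[:, 0].copy(), f.xyz[:, 1].copy(), f.xyz[:, 2]
        if f.box_xy is not None:  # wrap into the periodic box
            x %= f.box_xy[0]
            y %= f.box_xy[1]
        ix = np.clip(np.searchsorted(x_edges, x, side="right") - 1, 0, nx - 1)
        iy = np.clip(np.searchsorted(y_edges, y, side="right") - 1, 0, ny - 1)
        flat = ix * ny + iy
        zsum = {}
        for tag in (UPPER, LOWER):
            m = f.leaflet == tag
            s = np.bincount(flat[m], weights=z[m], minlength=nx * ny)
            c = np.bincount(flat[m], minlength=nx * ny)
            zsum[tag] = (s, c)
        su, cu = zsum[UPPER]
        sl, cl = zsum[LOWER]
        both = (cu > 0) & (cl > 0)
        d = np.zeros(nx * ny)
        d[both] = su[both] / cu[both] - sl[both] / cl[both]
        dist_sum += d.reshape(nx, ny)
        dist_cnt += both.reshape(nx, ny)

    mean = np.full((nx, ny), np.nan)
    pop = dist_cnt > 0
    mean[pop] = dist_sum[pop] / dist_cnt[pop]
    return ThicknessMap(x_edges, y_edges, mean, dist_cnt, len(sel), (start, end))


@dataclass
class ThinningSummary:
    bulk_thickness: float      # Å, mean over bins far from the minimum
    min_thickness: float       # Å
    min_bin: tuple[float, float]  # bin-center coordinates of the minimum
    max_thinning: float        # Å, bulk − min
    bulk_radius: float         # Å, bulk-region definition used
    n_bulk_bins: int


def thinning_summary(tmap: ThicknessMap, bulk_radius: float = 25.0) -> ThinningSummary:
    """Bulk thickness, the map minimum, and their difference (max thinning).

    The bulk region is the set of populated bins whose centers lie farther
    than ``bulk_radius`` from the bin holding the map minimum.
    """
    if not tmap.populated.any():
        raise ValueError("thickness map has no populated bins")
    vals = np.where(tmap.populated, tmap.mean, np.inf)
    i, j = np.unravel_index(np.argmin(vals), vals.shape)
    mn = float(tmap.mean[i, j])
    cx, cy = tmap.x_centers[i], tmap.y_centers[j]
    xx, yy = np.meshgrid(tmap.x_centers, tmap.y_centers, indexing="ij")
    r = np.hypot(xx - cx, yy - cy)
    bulk_mask = tmap.populated & (r > bulk_radius)
    if not bulk_mask.any():
        raise ValueError(
            f"no populated bins farther than {bulk_radius} Å from the minimum; map too small"
        )
    bulk = float(tmap.mean[bulk_mask].mean())
    return ThinningSummary(
        bulk_thickness=bulk, min_thickness=mn, min_bin=(float(cx), float(cy)),
        max_thinning=bulk - mn, bulk_radius=bulk_radius, n_bulk_bins=int(bulk_mask.sum()),
    )


@dataclass
class DifferenceResult:
    diff: np.ndarray                 # A − B per bin populated in both; NaN elsewhere
    delta_max_thinning: float        # thinning(A) − thinning(B)
    x_edges: np.ndarray = field(repr=False, default=None)
    y_edges: np.ndarray = field(repr=False, default=None)


def _resample_nearest(src: ThicknessMap, x_edges: np.ndarray, y_edges: np.ndarray) -> np.ndarray:
    """Nearest-bin resample of ``src.mean`` onto a target grid."""
    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    yc = 0.5 * (y_edges[:-1] + y_edges[1:])
    ix = np.clip(np.searchsorted(src.x_edges, xc, side="right") - 1, 0, len(src.x_centers) - 1)
    iy = np.clip(np.searchsorted(src.y_edges, yc, side="right") - 1, 0, len(src.y_centers) - 1)
    return src.mean[np.ix_(ix, iy)]


def difference_map(
    map_a: ThicknessMap, map_b: ThicknessMap, bulk_radius: float = 25.0
) -> DifferenceResult:
    """Per-bin A − B thickness difference and the difference in max thinning.

    Grids must agree; a mismatching B is resampled onto A's grid by the
    nearest-bin rule.  Bins populated in only one map are NaN in the output;
    fully disjoint populated sets raise ``ValueError``.
    """
    same = (
        len(map_a.x_edges) == len(map_b.x_edges)
        and len(map_a.y_edges) == len(map_b.y_edges)
        and np.allclose(map_a.x_edges, map_b.x_edges)
        and np.allclose(map_a.y_edges, map_b.y_edges)
    )
    b_mean = map_b.mean if same else _resample_nearest(map_b, map_a.x_edges, map_a.y_edges)
    both = np.isfinite(map_a.mean) & np.isfinite(b_mean)
    if not both.any():
        raise ValueError("maps have disjoint populated bins")
    diff = np.full_like(map_a.mean, np.nan)
    diff[both] = map_a.mean[both] - b_mean[both]
    dmax = (
        thinning_summary(map_a, bulk_radius).max_thinning
        - thinning_summary(map_b, bulk_radius).max_thinning
    )
    return DifferenceResult(diff=diff, delta_max_thinning=dmax,
                            x_edges=map_a.x_edges, y_edges=map_a.y_edges)


# ---------------------------------------------------------------------------
# frame I/O

def write_xyz_frames(frames: Iterable[BilayerFrame]) -> str:
    """XYZ-like text: per frame ``natoms`` / comment / ``tag x y z`` lines."""
    chunks = []
    for f in frames:
        comment = f"frame={f.index}"
        if f.time_ns is not None:
            comment += f" time_ns={f.time_ns:g}"
        if f.box_xy is not None:
            comment += f" box={f.box_xy[0]:g},{f.box_xy[1]:g}"
        lines = [str(f.n_points), comment]
        for tag, (x, y, z) in zip(f.leaflet, f.xyz):
            lines.append(f"{tag} {x:.4f} {y:.4f} {z:.4f}")
        chunks.append("\n".join(lines))
    return "\n".join(chunks) + "\n"


def read_xyz_frames(text: str) -> list[BilayerFrame]:
    lines = text.splitlines()
    frames: list[BilayerFrame] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        meta = dict(tok.split("=", 1) for tok in comment.split() if "=" in tok)
        box = None
        if "box" in meta:
            bx, by = meta["box"].split(",")
            box = (float(bx), float(by))
        body = lines[i + 2 : i + 2 + n]
        if len(body) < n:
            raise ValueError(f"truncated frame starting at line {i + 1}")
        tags, xyz = [], []
        for ln in body:
            tok = ln.split()
            tags.append(tok[0])
            xyz.append([float(tok[1]), float(tok[2]), float(tok[3])])
        frames.append(
            BilayerFrame(
                index=int(meta.get("frame", len(frames))),
                xyz=np.array(xyz),
                leaflet=np.array(tags, dtype="U10"),
                time_ns=float(meta["time_ns"]) if "time_ns" in meta else None,
                box_xy=box,
            )
        )
        i += 2 + n
    return frames


def write_pdb_frames(frames: Iterable[BilayerFrame]) -> str:
    """Multi-MODEL PDB; leaflet encoded in the chain id (U/L, X untagged)."""
    chain_of = {UPPER: "U", LOWER: "L", UNASSIGNED: "X"}
    out = []
    for f in frames:
        out.append(f"MODEL     {f.index + 1:4d}")
        for k, (tag, (x, y, z)) in enumerate(zip(f.leaflet, f.xyz), start=1):
            lid = int(f.lipid_id[k - 1]) % 10000
            out.append(
                f"ATOM  {k % 100000:5d}  P   LIP {chain_of[tag]}{lid:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           P"
            )
        out.append("ENDMDL")
    out.append("END")
    return "\n".join(out) + "\n"


def read_pdb_frames(text: str) -> list[BilayerFrame]:
    """Read MODEL blocks of ATOM/HETATM records; chain U/L carries the leaflet."""
    tag_of = {"U": UPPER, "L": LOWER}
    frames: list[BilayerFrame] = []
    cur_xyz: list[list[float]] = []
    cur_tag: list[str] = []
    cur_lid: list[int] = []
    in_model = False
    for line in text.splitlines():
        rec = line[:6]
        if rec.startswith("MODEL"):
            in_model, cur_xyz, cur_tag, cur_lid = True, [], [], []
        elif rec in ("ATOM  ", "HETATM"):
            if not in_model:  # single implicit model
                in_model = True
            cur_xyz.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
            cur_tag.append(tag_of.get(line[21], UNASSIGNED))
            try:
                cur_lid.append(int(line[22:26]))
            except ValueError:
                cur_lid.append(len(cur_lid))
        elif rec.startswith("ENDMDL") or rec.startswith("END"):
            if in_model and cur_xyz:
                frames.append(
                    BilayerFrame(
                        index=len(frames), xyz=np.array(cur_xyz),
                        leaflet=np.array(cur_tag, dtype="U10"),
                        lipid_id=np.array(cur_lid),
                    )
                )
            in_model = False
    if in_model and cur_xyz:
        frames.append(
            BilayerFrame(index=len(frames), xyz=np.array(cur_xyz),
                         leaflet=np.array(cur_tag, dtype="U10"), lipid_id=np.array(cur_lid))
        )
    return frames
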