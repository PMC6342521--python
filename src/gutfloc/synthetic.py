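"""Ground-truth synthetic data: aggregate-size samples and rendered z-stacks.

The generator stands in for the mouse-derived confocal data: it draws
aggregate sizes from a known law, renders each aggregate as a compact cluster
of touching fluorescent spheres inside the study's imaging geometry (a
200 x 200 x 40 µm volume sampled as 113 slices), applies an approximately
linear depth attenuation and a background + shot noise model, and quantizes
to 16 bit.  Because the size law and every rendered position are recorded,
the segmentation and statistics stages can be tested against exact truth.

All randomness flows from the single ``FixtureSpec.seed``; no global RNG
state is touched.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.stats import lognorm

from .aggstats import AggregateTable
from .errors import ConfigurationError, PlacementError
from .segmentation import ImageStack

__all__ = [
    "FixtureSpec",
    "population_vw_mean",
    "sample_aggregate_sizes",
    "render_stack",
    "generate_fixture_set",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic sample/stack.

    size_law + law_params name a distribution over N >= 1:
      * "point":     {"value": k}
      * "mixture":   {"values": (...), "weights": (...)} point-mass mixture
      * "geometric": {"p": p} on {1, 2, ...}
      * "lognormal": {"mu": m, "sigma": s}, rounded up to the next integer

    stack_shape is (slices, rows, cols); volume_um the physical extent
    (z, y, x) in µm.  attenuation = (front_scale, back_scale) defines the
    linear per-slice intensity decay; noise = (background mean, background
    sd, shot scale) where the shot term has sd = shot_scale * sqrt(signal).
    psf_fwhm_um is the Gaussian blur standing in for the confocal PSF
    (axial, lateral, lateral).
    """

    size_law: str = "mixture"
    law_params: dict = field(default_factory=lambda: {"values": (1, 6), "weights": (0.8, 0.2)})
    n_aggregates: int = 300
    stack_shape: tuple[int, int, int] = (113, 768, 768)
    volume_um: tuple[float, float, float] = (40.0, 200.0, 200.0)
    particle_diameter: float = 1.0
    attenuation: tuple[float, float] = (1.0, 0.5)
    noise: tuple[float, float, float] = (800.0, 120.0, 5.0)
    amplitude: float = 28000.0
    psf_fwhm_um: tuple[float, float, float] = (0.7, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        front, back = self.attenuation
        if not front >= back > 0:
            raise ValueError(f"attenuation must satisfy front >= back > 0, got {self.attenuation}")
        if self.n_aggregates < 1:
            raise ValueError("n_aggregates must be >= 1")
        if self.particle_diameter <= 0 or self.amplitude <= 0:
            raise ValueError("particle_diameter and amplitude must be > 0")
        if any(n < 1 for n in self.stack_shape) or any(v <= 0 for v in self.volume_um):
            raise ValueError("stack_shape and volume_um must be positive")

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        """(dz, dy, dx) in µm."""
        return tuple(v / n for v, n in zip(self.volume_um, self.stack_shape))


def _law_moments(spec: FixtureSpec) -> tuple[float, float]:
    """(E[N], E[N^2]) of the size law; summation for the rounded lognormal."""
    p = spec.law_params
    if spec.size_law == "point":
        v = float(p["value"])
        return v, v * v
    if spec.size_law == "mixture":
        vals = np.asarray(p["values"], dtype=float)
        w = np.asarray(p["weights"], dtype=float)
        w = w / w.sum()
        return float((w * vals).sum()), float((w * vals**2).sum())
    if spec.size_law == "geometric":
        q = float(p["p"])
        return 1.0 / q, (2.0 - q) / q**2
    if spec.size_law == "lognormal":
        dist = lognorm(s=p["sigma"], scale=math.exp(p["mu"]))
        # N = max(1, ceil(X)); sum P(N = k) k over a generous tail
        kmax = int(math.ceil(dist.ppf(1 - 1e-12))) + 1
        k = np.arange(1, kmax + 1)
        pk = dist.cdf(k) - dist.cdf(k - 1)
        pk[0] = dist.cdf(1.0)  # all mass below 1 maps to N = 1
        pk = pk / pk.sum()
        return float((pk * k).sum()), float((pk * k**2).sum())
    raise ConfigurationError(f"unknown size law {spec.size_law!r}")


def population_vw_mean(spec: FixtureSpec) -> float:
    """Population volume-weighted mean size ⟨N⟩ = E[N²]/E[N] of the law."""
    m1, m2 = _law_moments(spec)
    return m2 / m1


def sample_aggregate_sizes(spec: FixtureSpec, rng: np.random.Generator | None = None) -> AggregateTable:
    """Draw ``n_aggregates`` sizes from the spec's law, seeded by the spec."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    n = spec.n_aggregates
    p = spec.law_params
    if spec.size_law == "point":
        sizes = np.full(n, float(p["value"]))
    elif spec.size_law == "mixture":
        vals = np.asarray(p["values"], dtype=float)
        w = np.asarray(p["weights"], dtype=float)
        sizes = rng.choice(vals, size=n, p=w / w.sum())
    elif spec.size_law == "geometric":
        sizes = rng.geometric(float(p["p"]), size=n).astype(float)
    elif spec.size_law == "lognormal":
        sizes = np.maximum(np.ceil(rng.lognormal(p["mu"], p["sigma"], size=n)), 1.0)
    else:
        raise ConfigurationError(f"unknown size law {spec.size_law!r}")
    return AggregateTable(sizes, sample_label=f"synthetic:{spec.size_law}")


def _cluster_offsets(n: int, diameter: float, rng: np.random.Generator) -> np.ndarray:
    """Centers (µm) of n touching spheres, built by greedy contact addition."""
    centers = [np.zeros(3)]
    while len(centers) < n:
        placed = False
        for _ in range(500):
            base = centers[rng.integers(len(centers))]
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            cand = base + diameter * direction
            d = np.linalg.norm(np.asarray(centers) - cand, axis=1)
            if np.all(d >= diameter * 0.999):
                centers.append(cand)
                placed = True
                break
        if not placed:  # pragma: no cover - essentially unreachable for small n
            raise PlacementError(f"could not grow a {n}-sphere cluster")
    offsets = np.asarray(centers)
    return offsets - offsets.mean(axis=0)


def _rasterize_spheres(volume: np.ndarray, centers_um: np.ndarray, radius: float,
                       voxel: tuple[float, float, float]) -> int:
    """Draw soft-edged spheres into ``volume`` (max-combined).

    Returns the number of voxels of the union of these spheres whose
    coverage exceeds one half (the aggregate's rendered voxel volume).
    """
    edge = min(voxel)  # soft-edge width, one (finest) voxel
    shape = volume.shape
    # bounding box of the whole cluster
    lo = np.maximum(np.floor((centers_um.min(axis=0) - radius - 2 * edge) / voxel).astype(int), 0)
    hi = np.minimum(np.ceil((centers_um.max(axis=0) + radius + 2 * edge) / voxel).astype(int) + 1,
                    shape)
    local = np.zeros(tuple(hi - lo), dtype=np.float32)
    axes = [ (np.arange(lo[i], hi[i]) + 0.5) * voxel[i] for i in range(3) ]
    for c in centers_um:
        d = np.sqrt((axes[0][:, None, None] - c[0]) ** 2
                    + (axes[1][None, :, None] - c[1]) ** 2
                    + (axes[2][None, None, :] - c[2]) ** 2)
        f = np.clip((radius - d) / edge + 0.5, 0.0, 1.0).astype(np.float32)
        np.maximum(local, f, out=local)
    region = tuple(slice(lo[i], hi[i]) for i in range(3))
    np.maximum(volume[region], local, out=volume[region])
    return int((local > 0.5).sum())


def render_stack(table: AggregateTable, spec: FixtureSpec,
                 rng: np.random.Generator | None = None):
    """Render an aggregate table into a noisy, depth-attenuated 16-bit stack.

    Each aggregate becomes a cluster of ``N_i`` touching spheres placed by
    rejection so that no two aggregates overlap; the ideal volume is blurred
    with a Gaussian PSF, scaled per slice by the linear attenuation line,
    and corrupted with Gaussian background plus intensity-proportional shot
    noise.  Returns ``(ImageStack, ground_truth)`` where ground truth lists,
    per aggregate, its id, particle count, center and rendered voxel volume.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    shape = spec.stack_shape
    voxel = np.asarray(spec.voxel_size)
    vol_um = np.asarray(spec.volume_um, dtype=float)
    radius = spec.particle_diameter / 2.0

    sizes = np.round(table.sizes).astype(int)
    clusters = []
    for n_particles in sizes:
        offsets = _cluster_offsets(int(n_particles), spec.particle_diameter, rng)
        bound = float(np.linalg.norm(offsets, axis=1).max()) + radius
        clusters.append((offsets, bound))

    # place largest first: easier rejection packing
    order = np.argsort([-b for _, b in clusters])
    margin = 2.0 * min(voxel)
    placed: list[tuple[np.ndarray, float]] = []
    centers = np.empty((len(clusters), 3))
    for idx in order:
        offsets, bound = clusters[idx]
        lo = bound + margin
        hi = vol_um - bound - margin
        if np.any(hi <= lo):
            raise PlacementError("an aggregate is too large for the imaging volume")
        ok = False
        for _ in range(2000):
            cand = rng.uniform(lo, hi)
            if all(np.linalg.norm(cand - c) >= bound + b + 0.5 for c, b in placed):
                ok = True
                break
        if not ok:
            raise PlacementError(
                "could not place all aggregates without overlap; lower n_aggregates"
            )
        placed.append((cand, bound))
        centers[idx] = cand

    ideal = np.zeros(shape, dtype=np.float32)
    ground_truth = []
    for i, (offsets, _) in enumerate(clusters):
        nvox = _rasterize_spheres(ideal, centers[i] + offsets, radius, tuple(voxel))
        ground_truth.append({
            "aggregate_id": i,
            "n_particles": int(sizes[i]),
            "center_um": tuple(round(float(c), 4) for c in centers[i]),
            "rendered_voxels": nvox,
            "rendered_volume_um3": nvox * float(np.prod(voxel)),
        })

    sigma_vox = np.asarray(spec.psf_fwhm_um) / 2.3548 / voxel
    blurred = gaussian_filter(ideal, sigma=sigma_vox)

    front, back = spec.attenuation
    n_slices = shape[0]
    scale = front + (back - front) * np.arange(n_slices) / max(n_slices - 1, 1)
    signal = blurred * (spec.amplitude * scale[:, None, None]).astype(np.float32)

    bg_mean, bg_sd, shot = spec.noise
    out = signal
    if bg_sd > 0 or shot > 0:
        noise = rng.standard_normal(shape, dtype=np.float32)
        out = signal + noise * np.sqrt(bg_sd**2 + shot**2 * signal)
    out = out + bg_mean
    stack = ImageStack(
        np.clip(np.round(out), 0, 65535).astype(np.uint16),
        tuple(float(v) for v in voxel),
    )
    return stack, ground_truth


def generate_fixture_set(specs, out_dir) -> dict:
    """Write TIFFs + sidecars + ground-truth CSVs + a checksum manifest.

    Re-running with identical specs reproduces byte-identical outputs; the
    manifest records every seed and the sha256 of every file.
    """
    import pandas as pd
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, spec in enumerate(specs):
        name = f"fixture_{i:03d}"
        rng = np.random.default_rng(spec.seed)
        table = sample_aggregate_sizes(spec, rng)
        stack, truth = render_stack(table, spec, rng)

        tiff_path = out_dir / f"{name}.tif"
        tifffile.imwrite(tiff_path, stack.voxels, photometric="minisblack")
        sidecar_path = out_dir / f"{name}.json"
        sidecar = {"voxel_size_um": list(stack.voxel_size), "spec": asdict(spec)}
        sidecar_path.write_text(json.dumps(sidecar, sort_keys=True, default=list, indent=1))
        truth_path = out_dir / f"{name}_truth.csv"
        pd.DataFrame(truth).to_csv(truth_path, index=False)

        files = {}
        for path in (tiff_path, sidecar_path, truth_path):
            files[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
        entries.append({"name": name, "seed": spec.seed, "size_law": spec.size_law,
                        "n_aggregates": spec.n_aggregates, "files": files})
    manifest = {"fixtures": entries}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest
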