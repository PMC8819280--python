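"""Simulated cortical phosphene vision.

Converts a binary contour mask into the percept a cortical visual
prosthesis wearer is assumed to see: an n x n grid of binary phosphenes
rendered as equally sized white Gaussian blobs (sigma 2.0 px on a 480 px
display spanning ~35 deg of visual arc, i.e. roughly 0.3 deg per blob).
Biological irregularity is modeled by a temporally constant random jitter
of each phosphene's grid location and a temporally constant per-phosphene
brightness gain.

Phosphenes are strictly binary: a phosphene is either on (its blob is
drawn, scaled by its fixed gain) or off.  The mapping from the contour
mask to on/off states pools the mask over each phosphene's receptive
window (one grid cell centered on the jittered location); the default
``max_pool`` policy lights the phosphene if any mask pixel in the window
is set, which preserves thin 1-px contours at low grid resolutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhospheneGridSpec",
    "PhospheneMap",
    "PhospheneFrame",
    "build_phosphene_map",
    "activate",
    "render_phosphenes",
    "simulate_view",
    "blob_angular_size_deg",
]

STUDY_RESOLUTIONS = (10, 18, 26, 34, 42, 50)


@dataclass(frozen=True)
class PhospheneGridSpec:
    """Phosphene grid configuration.

    ``n`` is the grid side (the study used 10, 18, 26, 34, 42, 50);
    ``jitter_frac`` bounds the location distortion as a fraction of the
    grid pitch per axis; ``gain_sd`` is the spread of the per-phosphene
    brightness gain around 1 (clipped to [0.5, 1.5])."""

    n: int = 26
    display_px: int = 480
    fov_deg: float = 35.0
    blob_sigma_px: float = 2.0
    jitter_frac: float = 0.15
    gain_sd: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.blob_sigma_px <= 0:
            raise ValueError("blob_sigma_px must be positive")
        if not 0 <= self.jitter_frac < 0.5:
            raise ValueError("jitter_frac must be in [0, 0.5)")
        if self.gain_sd < 0:
            raise ValueError("gain_sd must be >= 0")

    @property
    def pitch(self) -> float:
        """Grid pitch in display pixels."""
        return self.display_px / self.n


@dataclass
class PhospheneMap:
    """Frozen per-phosphene state: base grid locations, jittered locations
    and brightness gains.  Regenerating with the same spec reproduces the
    map bit-for-bit."""

    spec: PhospheneGridSpec
    base_locations: np.ndarray  # (n*n, 2) pixel coords (row, col)
    locations: np.ndarray       # (n*n, 2) jittered pixel coords
    gains: np.ndarray           # (n*n,) positive multipliers


@dataclass
class PhospheneFrame:
    """One rendered percept: binary activations plus the display raster."""

    activations: np.ndarray  # (n*n,) bool
    image: np.ndarray        # (display_px, display_px) float in [0, 1]


def build_phosphene_map(spec: PhospheneGridSpec) -> PhospheneMap:
    """Lay out the jittered phosphene grid.

    Base locations are the cell centers of a uniform n x n partition of the
    display; jitter is uniform in +-jitter_frac * pitch per axis; gains are
    normal with mean 1 and sd ``gain_sd``, clipped to [0.5, 1.5].  All
    randomness comes from a generator seeded with ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    pitch = spec.pitch
    centers = (np.arange(spec.n) + 0.5) * pitch
    rows, cols = np.meshgrid(centers, centers, indexing="ij")
    base = np.column_stack([rows.ravel(), cols.ravel()])
    jitter = rng.uniform(-spec.jitter_frac, spec.jitter_frac, size=base.shape) * pitch
    gains = np.clip(rng.normal(1.0, spec.gain_sd, size=len(base)), 0.5, 1.5) if spec.gain_sd > 0 \
        else np.ones(len(base))
    return PhospheneMap(spec=spec, base_locations=base, locations=base + jitter, gains=gains)


def activate(
    pmap: PhospheneMap,
    mask: np.ndarray,
    policy: str = "max_pool",
    mean_threshold: float = 0.5,
) -> np.ndarray:
    """Binary phosphene states from a contour mask.

    Each phosphene owns a square receptive window of side = pitch centered
    on its jittered location (clipped at the display borders).
    ``max_pool``: on iff any window pixel is set; ``mean_pool``: on iff the
    window mean is at least ``mean_threshold``."""
    spec = pmap.spec
    if mask.shape != (spec.display_px, spec.display_px):
        raise ValueError(
            f"mask shape {mask.shape} does not match display "
            f"({spec.display_px}, {spec.display_px})"
        )
    if policy not in ("max_pool", "mean_pool"):
        raise ValueError(f"unknown pooling policy {policy!r}")
    mask = mask.astype(bool)
    half = spec.pitch / 2
    out = np.zeros(len(pmap.locations), dtype=bool)
    for i, (r, c) in enumerate(pmap.locations):
        r0 = max(int(np.floor(r - half + 0.5)), 0)
        r1 = min(int(np.floor(r + half + 0.5)), spec.display_px)
        c0 = max(int(np.floor(c - half + 0.5)), 0)
        c1 = min(int(np.floor(c + half + 0.5)), spec.display_px)
        if r1 <= r0 or c1 <= c0:
            continue
        window = mask[r0:r1, c0:c1]
        out[i] = window.any() if policy == "max_pool" else window.mean() >= mean_threshold
    return out


def render_phosphenes(
    pmap: PhospheneMap,
    activations: np.ndarray,
    *,
    truncate_sigmas: float = 4.0,
) -> PhospheneFrame:
    """Draw active phosphenes as Gaussian blobs.

    image = clip(sum over active phosphenes of gain * exp(-d^2 / 2 sigma^2))
    with each blob truncated at ``truncate_sigmas`` * sigma."""
    spec = pmap.spec
    activations = np.asarray(activations, dtype=bool)
    if activations.shape != (len(pmap.locations),):
        raise ValueError("activations length does not match phosphene count")
    size = spec.display_px
    sigma = spec.blob_sigma_px
    rad = int(np.ceil(truncate_sigmas * sigma))
    image = np.zeros((size, size))
    for (r, c), gain in zip(pmap.locations[activations], pmap.gains[activations]):
        r0, r1 = max(int(np.floor(r)) - rad, 0), min(int(np.floor(r)) + rad + 1, size)
        c0, c1 = max(int(np.floor(c)) - rad, 0), min(int(np.floor(c)) + rad + 1, size)
        if r1 <= r0 or c1 <= c0:
            continue
        rr = np.arange(r0, r1) + 0.5
        cc = np.arange(c0, c1) + 0.5
        d2 = (rr[:, None] - r) ** 2 + (cc[None, :] - c) ** 2
        blob = gain * np.exp(-d2 / (2 * sigma**2))
        blob[d2 > (truncate_sigmas * sigma) ** 2] = 0.0
        image[r0:r1, c0:c1] += blob
    return PhospheneFrame(activations=activations, image=np.clip(image, 0.0, 1.0))


def simulate_view(
    frame_or_view,
    spec: PhospheneGridSpec,
    method: str = "ced",
    *,
    pmap: PhospheneMap | None = None,
    policy: str = "max_pool",
    mean_threshold: float = 0.5,
    **contour_kwargs,
) -> PhospheneFrame:
    """Full pipeline: contour extraction -> activation -> blob rendering.

    Pass a prebuilt ``pmap`` to reuse one phosphene map across the frames
    of a stream (jitter and gains are temporally constant)."""
    from .contours import extract_contours

    mask = extract_contours(frame_or_view, method, **contour_kwargs)
    if pmap is None:
        pmap = build_phosphene_map(spec)
    acts = activate(pmap, mask, policy=policy, mean_threshold=mean_threshold)
    return render_phosphenes(pmap, acts)


def blob_angular_size_deg(spec: PhospheneGridSpec) -> float:
    """Nominal phosphene angular diameter (2 sigma) in degrees of visual arc."""
    return 2.0 * spec.blob_sigma_px * spec.fov_deg / spec.display_px
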