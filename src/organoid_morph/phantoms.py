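"""Synthetic brightfield organoid phantoms with ground-truth masks.

A phantom is a dark, roughly convex silhouette on a bright field, the
appearance of a transmitted-light image of a dense 3-D organoid.  The
boundary is defined in polar form

    r(theta) = R * (1 + a * sum_m a_m cos(m*theta + phi_m))

with the Fourier coefficients ``a_m`` and phases ``phi_m`` drawn from a
seeded RNG and normalised so the perturbation has unit RMS; the single
scalar ``irregularity_amplitude`` then controls the true circularity
monotonically, which is what makes ordering and monotonicity tests
possible.  Optical blur, additive Gaussian noise and an optional
multiplicative vignette are applied on top; the ground-truth mask is
the unblurred interior.

A :class:`PhantomSeries` strings phantoms along a saturating growth
curve ``radius(day) = r_max * day / (t_half + day)`` with boundary
irregularity increasing linearly in time -- steep early growth that
plateaus, and roundness that slowly degrades.  This is a phantom
convenience, not a biological growth model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .image_io import GrayImage, ImageRecord
from .segmentation import OrganoidMask

#: Imaging schedule emulated by default series: daily for the first 21
#: days, then every 3 days until day 42 (28 timepoints).
def paper_schedule() -> list[int]:
    return list(range(1, 22)) + list(range(24, 43, 3))


@dataclass
class PhantomSpec:
    """Generative parameters for one synthetic organoid image."""

    radius_px: float
    irregularity_amplitude: float = 0.0
    irregularity_modes: tuple[int, int] = (2, 8)
    organoid_intensity: float = 40.0
    background_intensity: float = 200.0
    noise_sd: float = 5.0
    blur_sd_px: float = 2.0
    vignette_strength: float = 0.0
    image_size_px: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.radius_px > 0:
            raise ValidationError("radius_px must be > 0")
        if not 0 <= self.irregularity_amplitude < 0.5:
            raise ValidationError("irregularity_amplitude must lie in [0, 0.5)")
        lo, hi = self.irregularity_modes
        if lo < 1 or hi < lo:
            raise ValidationError("irregularity_modes must be an increasing range of modes >= 1")
        for name in ("organoid_intensity", "background_intensity"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValidationError(f"{name} must lie in [0, 255]")
        if self.noise_sd < 0 or self.blur_sd_px < 0:
            raise ValidationError("noise_sd and blur_sd_px must be >= 0")
        if not 0 <= self.vignette_strength <= 0.3:
            raise ValidationError("vignette_strength must lie in [0, 0.3]")
        if self.image_size_px is None:
            # unit-RMS Fourier perturbations peak above 1, so leave a
            # 3x-amplitude margin plus a fixed border buffer
            self.image_size_px = (
                int(np.ceil(2 * self.radius_px * (1 + 3 * self.irregularity_amplitude))) + 40
            )
        max_r = self.radius_px * (1 + self.irregularity_amplitude)
        if not max_r < self.image_size_px / 2:
            raise ValidationError(
                f"radius {self.radius_px} x (1+amplitude) = {max_r:.1f} px must be "
                f"smaller than half the image size ({self.image_size_px}/2); the "
                "organoid may not contact the border"
            )


def generate_phantom(spec: PhantomSpec) -> tuple[GrayImage, OrganoidMask]:
    """Render one phantom; deterministic for a fixed spec (incl. seed)."""
    rng = np.random.default_rng(spec.seed)
    modes = np.arange(spec.irregularity_modes[0], spec.irregularity_modes[1] + 1)
    coeffs = rng.normal(size=len(modes))
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(modes))
    # Unit-RMS normalisation of the angular perturbation:
    # RMS over theta of sum a_m cos(m theta + phi_m) is sqrt(sum a_m^2 / 2).
    norm = np.sqrt(np.sum(coeffs**2) / 2.0)
    if norm > 0:
        coeffs = coeffs / norm

    n = spec.image_size_px
    yy, xx = np.mgrid[:n, :n]
    c = (n - 1) / 2.0
    rho = np.hypot(yy - c, xx - c)
    theta = np.arctan2(yy - c, xx - c)
    perturb = np.zeros_like(theta)
    for m, a, ph in zip(modes, coeffs, phases):
        perturb += a * np.cos(m * theta + ph)
    r_boundary = spec.radius_px * (1.0 + spec.irregularity_amplitude * perturb)
    truth = rho <= r_boundary

    img = np.where(truth, spec.organoid_intensity, spec.background_intensity)
    if spec.vignette_strength > 0:
        d_max = np.hypot(c, c)
        img = img * (1.0 - spec.vignette_strength * (rho / d_max) ** 2)
    if spec.blur_sd_px > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sd_px, mode="reflect")
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 255.0)
    return GrayImage(img), OrganoidMask(truth)


@dataclass
class PhantomSeries:
    """A labelled time series of phantom specs for one cell line."""

    cell_line: str
    entries: list[tuple[int, PhantomSpec]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.cell_line:
            raise ValidationError("cell_line must be non-empty")
        days = [d for d, _ in self.entries]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValidationError("days must be strictly increasing")
        radii = [s.radius_px for _, s in self.entries]
        if any(b < a for a, b in zip(radii, radii[1:])):
            raise ValidationError("radius must be non-decreasing over days")

    @classmethod
    def from_growth_model(
        cls,
        cell_line: str,
        days: list[int] | None = None,
        r_max_px: float = 100.0,
        t_half_days: float = 6.0,
        amplitude_per_day: float = 0.003,
        base_seed: int = 0,
        **phantom_kwargs,
    ) -> "PhantomSeries":
        """Build a series from the saturating growth model.

        ``radius(day) = r_max * day / (t_half + day)`` gives the
        steepest growth in the earliest interval and a plateau later;
        irregularity grows linearly at ``amplitude_per_day`` (capped at
        0.3).  Each entry gets its own sub-seed derived from
        ``base_seed`` so series are reproducible element-wise.
        """
        if days is None:
            days = paper_schedule()
        image_size = int(np.ceil(2 * r_max_px * 1.3)) + 4
        entries = []
        for idx, day in enumerate(days):
            seed = int(
                np.random.SeedSequence([base_seed, idx]).generate_state(1)[0] % (2**31)
            )
            spec = PhantomSpec(
                radius_px=r_max_px * day / (t_half_days + day),
                irregularity_amplitude=min(amplitude_per_day * day, 0.3),
                image_size_px=image_size,
                seed=seed,
                **phantom_kwargs,
            )
            entries.append((day, spec))
        return cls(cell_line=cell_line, entries=entries)


def generate_series(
    series: PhantomSeries,
) -> list[tuple[ImageRecord, GrayImage, OrganoidMask]]:
    """Render every entry of a series with manifest records attached."""
    out = []
    for day, spec in series.entries:
        image, truth = generate_phantom(spec)
        record = ImageRecord(
            file_path=f"{series.cell_line}_day{day:03d}.png",
            cell_line=series.cell_line,
            day=day,
        )
        out.append((record, image, truth))
    return out
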