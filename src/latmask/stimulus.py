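"""Gabor stimulus rendering and display geometry.

Stimuli are vertical Gabor patches — a sinusoidal carrier windowed by an
isotropic Gaussian — on a mid-grey background.  Luminance is expressed in
normalised units [0, 1] with background 0.5:

    L(u, v) = 0.5 * (1 + c * cos(2 pi f u + phase) * exp(-(u^2+v^2)/(2 sigma^2)))

with ``u`` along the modulation axis (horizontal for a vertical grating),
``c`` the Michelson contrast and ``f`` the spatial frequency in cycles per
degree.  Collinear flankers sit above and below the target at multiples of
the carrier wavelength; overlapping patches add in contrast-modulation space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import ValidationError

__all__ = [
    "GaborSpec",
    "DisplayGeometry",
    "TrialFrame",
    "deg_to_px",
    "render_gabor",
    "compose_trial",
    "required_image_size",
    "contact_sheet",
]


@dataclass(frozen=True)
class GaborSpec:
    """Gabor patch parameters (angular units)."""

    spatial_frequency: float = 4.0   # cycles per degree
    orientation: float = 0.0         # degrees from vertical
    phase: float = 0.0               # radians, cosine phase
    contrast: float = 0.6            # Michelson proportion
    envelope_sigma: float = 0.25     # degrees; default = one wavelength at 4 cpd

    def __post_init__(self) -> None:
        if self.spatial_frequency <= 0:
            raise ValidationError("spatial frequency must be positive")
        if not (0.0 <= self.contrast <= 1.0):
            raise ValidationError("contrast must lie in [0, 1]")
        if self.envelope_sigma <= 0:
            raise ValidationError("envelope sigma must be positive")

    @property
    def wavelength(self) -> float:
        """Carrier wavelength in degrees: 1 / spatial frequency."""
        return 1.0 / self.spatial_frequency


@dataclass(frozen=True)
class DisplayGeometry:
    """Angular-to-pixel mapping of the display."""

    arcmin_per_pixel: float = 0.7
    mean_luminance: float = 0.5   # normalised units
    image_size: int = 512         # pixels, square frame

    def __post_init__(self) -> None:
        if self.arcmin_per_pixel <= 0:
            raise ValidationError("arcmin_per_pixel must be positive")
        if not (0.0 < self.mean_luminance < 1.0):
            raise ValidationError("mean luminance must lie in (0, 1)")
        if self.image_size < 1:
            raise ValidationError("image size must be >= 1 pixel")


@dataclass
class TrialFrame:
    """Rendered frame: luminance image plus component-centre annotations."""

    image: np.ndarray
    annotations: dict

    def michelson_contrast(self, mean_luminance: float = 0.5) -> float:
        """Michelson contrast of the underlying grating.

        Measured as the peak relative deviation from the background,
        ``max |L/L0 - 1|``: for a windowed grating this estimates the carrier
        amplitude at the envelope peak, which is the grating's Michelson
        contrast.  The raw frame statistic (Lmax-Lmin)/(Lmax+Lmin) would
        systematically understate it, because the Gaussian window attenuates
        the nearest luminance trough.
        """
        return float(np.abs(self.image / mean_luminance - 1.0).max())


def deg_to_px(geom: DisplayGeometry, extent: float) -> float:
    """Convert an angular extent in degrees to (fractional) pixels.

    Rounding to integer pixels happens only at placement time, using
    round-half-away-from-zero.
    """
    if extent < 0:
        raise ValidationError("angular extent must be non-negative")
    return extent * 60.0 / geom.arcmin_per_pixel


def _round_half_away(x: float) -> int:
    return int(np.sign(x) * np.floor(np.abs(x) + 0.5))


def _modulation(spec: GaborSpec, geom: DisplayGeometry, center_deg=(0.0, 0.0)) -> np.ndarray:
    """Contrast-modulation field c * carrier * envelope over the frame."""
    n = geom.image_size
    px_deg = geom.arcmin_per_pixel / 60.0
    c = (n - 1) / 2.0
    xs = (np.arange(n) - c) * px_deg
    x, y = np.meshgrid(xs - center_deg[0], xs - center_deg[1])
    theta = np.deg2rad(spec.orientation)
    # vertical grating (orientation 0): modulation along the horizontal axis
    u = x * np.cos(theta) + y * np.sin(theta)
    carrier = np.cos(2.0 * np.pi * spec.spatial_frequency * u + spec.phase)
    envelope = np.exp(-(x**2 + y**2) / (2.0 * spec.envelope_sigma**2))
    return spec.contrast * carrier * envelope


def render_gabor(spec: GaborSpec, geom: DisplayGeometry | None = None) -> TrialFrame:
    """Render a single centred Gabor patch."""
    geom = geom or DisplayGeometry()
    m = _modulation(spec, geom)
    return _frame_from_modulation(m, geom, {"target": (0.0, 0.0)})


def _frame_from_modulation(m: np.ndarray, geom: DisplayGeometry, annotations: dict) -> TrialFrame:
    peak = np.abs(m).max()
    if geom.mean_luminance * (1.0 + peak) > 1.0 or geom.mean_luminance * (1.0 - peak) < 0.0:
        raise ValidationError(
            f"combined modulation {peak:.3f} would drive luminance outside [0, 1]"
        )
    image = geom.mean_luminance * (1.0 + m)
    return TrialFrame(image=image, annotations=annotations)


def required_image_size(
    flanker: GaborSpec, distance_lambda: float, geom: DisplayGeometry, n_sigma: float = 4.0
) -> int:
    """Smallest square frame holding flankers at the given distance + margin."""
    half_extent = distance_lambda * flanker.wavelength + n_sigma * flanker.envelope_sigma
    return 2 * _round_half_away(deg_to_px(geom, half_extent)) + 1


def compose_trial(
    target: GaborSpec | None,
    flanker: GaborSpec,
    distance_lambda: float,
    geom: DisplayGeometry | None = None,
) -> TrialFrame:
    """Compose a 2AFC interval: optional central target plus two flankers.

    Flankers are centred ``distance_lambda`` flanker wavelengths above and
    below the frame centre.  A ``target=None`` frame is the blank interval
    (flankers only).  Overlapping patches sum in modulation space; a sum that
    would exceed the luminance range raises.
    """
    geom = geom or DisplayGeometry()
    if distance_lambda <= 0:
        raise ValidationError("flanker distance must be positive wavelengths")
    offset_deg = distance_lambda * flanker.wavelength
    min_size = required_image_size(flanker, distance_lambda, geom)
    if geom.image_size < min_size:
        raise ValidationError(
            f"flankers at {distance_lambda} wavelengths need image_size >= {min_size} px "
            f"(got {geom.image_size})"
        )
    m = np.zeros((geom.image_size, geom.image_size))
    annotations: dict = {
        "flankers": [(0.0, -offset_deg), (0.0, offset_deg)],
        "distance_lambda": distance_lambda,
    }
    for cy in (-offset_deg, offset_deg):
        m += _modulation(flanker, geom, center_deg=(0.0, cy))
    if target is not None:
        m += _modulation(target, geom)
        annotations["target"] = (0.0, 0.0)
    return _frame_from_modulation(m, geom, annotations)


def contact_sheet(
    design_distances,
    target: GaborSpec | None = None,
    flanker: GaborSpec | None = None,
    geom: DisplayGeometry | None = None,
):
    """Matplotlib figure with the baseline and every flanker condition."""
    import matplotlib.pyplot as plt

    target = target or GaborSpec(contrast=0.09)
    flanker = flanker or GaborSpec()
    if geom is None:
        size = required_image_size(flanker, max(design_distances), DisplayGeometry())
        geom = DisplayGeometry(image_size=size)
    panels = [("baseline", render_gabor(target, geom))]
    panels += [
        (f"{d:g}λ", compose_trial(target, flanker, d, geom)) for d in design_distances
    ]
    fig, axes = plt.subplots(1, len(panels), figsize=(2.2 * len(panels), 2.4))
    for ax, (title, frame) in zip(np.atleast_1d(axes), panels):
        ax.imshow(frame.image, cmap="gray", vmin=0, vmax=1)
        ax.set_title(title, fontsize=9)
        ax.axis("off")
    fig.tight_layout()
    return fig
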