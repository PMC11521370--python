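"""Session configuration and consistency checks.

The imaging raster fixes the unit system: a 512x512-pixel video at 30 Hz
covering 0.85 x 0.85 deg gives ~600 pixels per degree, i.e. 0.1 arcmin per
pixel; strip-wise stabilization at 32 strips per frame yields gaze samples
at 30 x 32 = 960 Hz.  ``config_consistency`` recomputes these derived
quantities and flags disagreements with the declared values.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["SessionConfig", "config_consistency", "load_config", "save_config"]


@dataclass
class SessionConfig:
    """All raster, optics, and module parameters of one session."""

    pixel_scale_arcmin: float = 0.1
    field_deg: float = 0.85
    frame_rate_hz: float = 30.0
    strips_per_frame: int = 32
    image_pixels: int = 512
    wavelength_nm: float = 788.0
    pupil_diameter_mm: float = 7.0
    density_k: int = 150
    cdc_top_fraction: float = 0.20
    aperture_fraction: float = 0.48
    interaction_threshold: float = 0.01
    nyquist_row_factor: float = 0.8660254037844386
    seed: int = 0
    extra: dict = field(default_factory=dict)

    @property
    def strip_rate_hz(self) -> float:
        return self.frame_rate_hz * self.strips_per_frame

    @property
    def pixels_per_degree(self) -> float:
        return 60.0 / self.pixel_scale_arcmin

    @property
    def field_arcmin(self) -> float:
        return self.field_deg * 60.0


def config_consistency(config: SessionConfig) -> dict:
    """Recompute derived raster quantities and check declared values.

    Returns a report dict with the derived strip sampling rate (Hz), pixels
    per degree from the pixel scale, and pixels per degree implied by the
    image size over the field; entries whose disagreement exceeds 1% are
    listed under ``warnings``.
    """
    derived_ppd = config.pixels_per_degree
    implied_ppd = config.image_pixels / config.field_deg
    report = {
        "strip_rate_hz": config.strip_rate_hz,
        "pixels_per_degree": derived_ppd,
        "pixels_per_degree_from_field": implied_ppd,
        "warnings": [],
    }
    rel = abs(implied_ppd - derived_ppd) / derived_ppd
    if rel > 0.01:
        report["warnings"].append(
            f"image size / field implies {implied_ppd:.1f} px/deg but pixel "
            f"scale declares {derived_ppd:.1f} px/deg ({100 * rel:.1f}% apart)")
    elif rel > 0:
        report["note"] = (
            f"{implied_ppd:.1f} px/deg from image/field is within rounding of "
            f"the declared {derived_ppd:.0f} px/deg")
    return report


def load_config(path: str | Path) -> SessionConfig:
    """Read a YAML or JSON config file into a SessionConfig."""
    path = Path(path)
    text = path.read_text()
    data = (json.loads(text) if path.suffix.lower() == ".json"
            else yaml.safe_load(text))
    known = {f for f in SessionConfig.__dataclass_fields__}
    kwargs = {k: v for k, v in data.items() if k in known}
    extra = {k: v for k, v in data.items() if k not in known}
    if extra:
        kwargs.setdefault("extra", {}).update(extra)
    return SessionConfig(**kwargs)


def save_config(config: SessionConfig, path: str | Path) -> None:
    path = Path(path)
    data = asdict(config)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
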