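"""Image-quality metrics used by the tuners and the evaluation harness."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .geometry import ImageVolume

__all__ = [
    "MetricReport",
    "correlation_coefficient",
    "uqi",
    "relative_error",
    "rmse",
    "evaluate",
]


def _as_array(x) -> np.ndarray:
    if isinstance(x, ImageVolume):
        return x.values
    return np.asarray(x, dtype=np.float64)


def _pair(recon, reference) -> tuple[np.ndarray, np.ndarray]:
    a = _as_array(recon).ravel().astype(np.float64)
    b = _as_array(reference).ravel().astype(np.float64)
    if a.shape != b.shape:
        raise ValueError("recon and reference must have identical shapes")
    return a, b


def correlation_coefficient(recon, reference) -> float:
    """Pearson correlation Cov(recon, ref) / (sd_recon * sd_ref), in [-1, 1].

    Raises ``ValueError`` if either image has zero variance (undefined).
    """
    a, b = _pair(recon, reference)
    am, bm = a - a.mean(), b - b.mean()
    sa, sb = np.sqrt((am * am).mean()), np.sqrt((bm * bm).mean())
    if sa == 0.0 or sb == 0.0:
        raise ValueError("correlation undefined: an input has zero variance")
    cc = float((am * bm).mean() / (sa * sb))
    return min(1.0, max(-1.0, cc))


def uqi(recon, reference) -> float:
    """Universal quality index: the product of the covariance/variance term
    ``2 cov / (var + var_ref)`` and the luminance term
    ``2 m m_ref / (m^2 + m_ref^2)``."""
    a, b = _pair(recon, reference)
    ma, mb = a.mean(), b.mean()
    va = ((a - ma) ** 2).mean()
    vb = ((b - mb) ** 2).mean()
    cov = ((a - ma) * (b - mb)).mean()
    var_term_den = va + vb
    lum_term_den = ma * ma + mb * mb
    if var_term_den == 0.0 or lum_term_den == 0.0:
        raise ValueError("UQI undefined: zero denominator")
    return float((2.0 * cov / var_term_den) * (2.0 * ma * mb / lum_term_den))


def relative_error(recon, reference) -> float:
    """Relative 2-norm error ``||recon - ref|| / ||ref||`` (fraction)."""
    a, b = _pair(recon, reference)
    nb = float(np.linalg.norm(b))
    if nb == 0.0:
        raise ValueError("relative error undefined: reference is zero")
    return float(np.linalg.norm(a - b) / nb)


def rmse(a, b) -> float:
    """Root-mean-square error ``sqrt(mean((a - b)**2))``."""
    x, y = _pair(a, b)
    return float(np.sqrt(((x - y) ** 2).mean()))


@dataclass(frozen=True)
class MetricReport:
    """Metric bundle for one reconstruction against a reference."""

    cc: float
    uqi: float
    relative_error: float
    rmse: float

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    def as_dict(self) -> dict:
        return asdict(self)


def evaluate(recon, reference) -> MetricReport:
    """All image-domain metrics of ``recon`` against ``reference``."""
    return MetricReport(
        cc=correlation_coefficient(recon, reference),
        uqi=uqi(recon, reference),
        relative_error=relative_error(recon, reference),
        rmse=rmse(recon, reference),
    )
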