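"""Acquisition-protocol arithmetic and parameter recommendations.

The default :class:`AcquisitionProtocol` describes a 3D spoiled multi-echo
gradient-echo (FLASH-type) acquisition of the lumbosacral cord at 3 T:
20 axial slices of 5 mm, 0.5 x 0.5 mm^2 in-plane, TR 38 ms, five echoes
starting at 6.85 ms with 4 ms spacing, flip angle 8 deg, and 8 individually
exported magnitude repetitions (no k-space averaging).

The scan-time model is anchored to the measured total of the full protocol
(17:56 min for 5 echoes, 8 averages, i.e. 134.5 s per repetition) and scales
the per-repetition time with the minimum TR achievable for a shorter echo
train, ``TR_min(n) = TR - (E - n) * echo_spacing``.  Reference lines, dummy
scans and slice oversampling are not modelled separately; totals for six
averages reproduce the measured 10:38 (3 echoes) and 13:28 (5 echoes)
within one second of rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcquisitionProtocol",
    "Recommendation",
    "te_ladder",
    "scan_time",
    "recommend",
]


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Timing and geometry of a spoiled multi-echo gradient-echo scan."""

    tr_ms: float = 38.0
    te1_ms: float = 6.85
    echo_spacing_ms: float = 4.0
    n_echoes: int = 5
    flip_deg: float = 8.0
    in_plane_mm: float = 0.5
    matrix: tuple[int, int] = (384, 384)
    n_slices: int = 20
    slice_thickness_mm: float = 5.0
    n_repetitions: int = 8
    parallel_factor: int = 2
    rep_time_s: float = 134.5

    def __post_init__(self) -> None:
        positive = {
            "tr_ms": self.tr_ms,
            "te1_ms": self.te1_ms,
            "n_echoes": self.n_echoes,
            "flip_deg": self.flip_deg,
            "in_plane_mm": self.in_plane_mm,
            "n_slices": self.n_slices,
            "slice_thickness_mm": self.slice_thickness_mm,
            "n_repetitions": self.n_repetitions,
            "parallel_factor": self.parallel_factor,
            "rep_time_s": self.rep_time_s,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.echo_spacing_ms < 0:
            raise ValueError("echo_spacing_ms must be non-negative")
        # last echo must be read out before the next excitation
        last_te = self.te1_ms + (self.n_echoes - 1) * self.echo_spacing_ms
        if last_te >= self.tr_ms:
            raise ValueError(
                f"echo train (last TE {last_te} ms) does not fit within TR {self.tr_ms} ms"
            )

    @property
    def te_ladder_ms(self) -> np.ndarray:
        return te_ladder(self)

    @property
    def flip_rad(self) -> float:
        return float(np.deg2rad(self.flip_deg))


def te_ladder(protocol: AcquisitionProtocol) -> np.ndarray:
    """Echo times in ms: ``TE_i = TE_1 + (i - 1) * spacing``, i = 1..E."""
    i = np.arange(protocol.n_echoes, dtype=float)
    return protocol.te1_ms + i * protocol.echo_spacing_ms


def scan_time(
    protocol: AcquisitionProtocol,
    n_echoes: int | None = None,
    nsa: int | None = None,
) -> float:
    """Total acquisition time in seconds for ``nsa`` averages of ``n_echoes``.

    Linear in NSA; acquiring fewer echoes shortens the repetition time in
    proportion to ``TR_min(n) = TR - (E - n) * echo_spacing``.
    """
    if n_echoes is None:
        n_echoes = protocol.n_echoes
    if nsa is None:
        nsa = protocol.n_repetitions
    if not 1 <= n_echoes <= protocol.n_echoes:
        raise ValueError(f"n_echoes must be in 1..{protocol.n_echoes}, got {n_echoes}")
    if nsa < 1:
        raise ValueError(f"nsa must be >= 1, got {nsa}")
    tr_min = protocol.tr_ms - (protocol.n_echoes - n_echoes) * protocol.echo_spacing_ms
    return protocol.rep_time_s * nsa * tr_min / protocol.tr_ms


_VALID_INTENTS = ("sc", "gm", "joint")
_VALID_REGIONS = ("lse", "cm")

#: echoes to combine per (intent, region); minimum NSA is 6 throughout
_ECHO_RULES: dict[tuple[str, str], int] = {
    ("sc", "lse"): 5,
    ("sc", "cm"): 5,
    ("gm", "lse"): 3,
    ("gm", "cm"): 4,
    ("joint", "lse"): 3,
    ("joint", "cm"): 3,
}

_RATIONALES = {
    "sc": (
        "Cord segmentation relies on WM/CSF contrast, which keeps rising with "
        "echo time; combining all 5 echoes maximises WM/CSF CNR and cord "
        "segmentability."
    ),
    "gm": (
        "Gray matter segmentation relies on GM/WM contrast, which grows only "
        "mildly with echo time while SNR falls; 3 combined echoes are optimal "
        "in the lumbosacral enlargement, 4 in the conus medullaris."
    ),
    "joint": (
        "For segmenting cord and gray matter in the same image, 3 combined "
        "echoes trade a small WM/CSF CNR loss for near-optimal GM/WM CNR."
    ),
}


@dataclass(frozen=True)
class Recommendation:
    """Recommended echo combination and averaging for a segmentation intent."""

    intent: str
    region: str
    n_combined_echoes: int
    min_nsa: int = 6
    rationale: str = field(default="", repr=False)


def recommend(intent: str, region: str = "lse") -> Recommendation:
    """Recommended number of combined echoes and minimum NSA.

    Parameters
    ----------
    intent : {'sc', 'gm', 'joint'}
        Whether the image is meant for spinal-cord-only, gray-matter-only,
        or joint SC+GM segmentation.
    region : {'lse', 'cm'}
        Lumbosacral enlargement or conus medullaris.
    """
    intent = intent.lower()
    region = region.lower()
    if intent not in _VALID_INTENTS:
        raise ValueError(f"unknown intent {intent!r}; expected one of {_VALID_INTENTS}")
    if region not in _VALID_REGIONS:
        raise ValueError(f"unknown region {region!r}; expected one of {_VALID_REGIONS}")
    return Recommendation(
        intent=intent,
        region=region,
        n_combined_echoes=_ECHO_RULES[(intent, region)],
        min_nsa=6,
        rationale=_RATIONALES[intent],
    )
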