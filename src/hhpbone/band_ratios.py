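"""Band-derived ratios: relative gene expression and collagen chain ratio.

Relative expression of an RT-PCR product is the treated band volume over
the control band volume (1.0 = control level); an absent treated band is
"not detectable" (n.d.), which is missing data, not zero. Collagen type I
is a triple helix of two alpha-1 chains and one alpha-2 chain, so on an
SDS-PAGE of intact bone matrix the alpha-1:alpha-2 band-volume ratio is
expected to be 2.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import AmbiguityError, ConfigError, IdentificationError
from .gel_densitometry import BandCall, LadderCalibration

__all__ = [
    "ExpressionResult",
    "AlphaChainRatio",
    "relative_expression",
    "alpha_chain_ratio",
    "identify_alpha_bands",
]

#: Stoichiometric alpha-1:alpha-2 reference of collagen type I.
EXPECTED_ALPHA_RATIO: float = 2.0


@dataclass
class ExpressionResult:
    """Relative expression of one gene (fraction of control level)."""

    gene: str
    treated_volume: float | None
    control_volume: float
    ratio: float | None  # None when not detectable
    detectable: bool

    def __str__(self) -> str:
        if not self.detectable:
            return f"{self.gene}: n.d."
        return f"{self.gene}: {self.ratio:.3g}x control"


@dataclass
class AlphaChainRatio:
    alpha1_volume: float
    alpha2_volume: float
    ratio: float
    expected: float = EXPECTED_ALPHA_RATIO


def relative_expression(
    treated_volume: float | None, control_volume: float, gene: str = ""
) -> ExpressionResult:
    """Treated/control band-volume ratio; absent treated band -> n.d."""
    if control_volume is None or control_volume <= 0:
        raise ConfigError(
            f"control band volume must be > 0 to define relative expression "
            f"(got {control_volume!r})"
        )
    if treated_volume is None:
        return ExpressionResult(
            gene=gene,
            treated_volume=None,
            control_volume=float(control_volume),
            ratio=None,
            detectable=False,
        )
    if treated_volume < 0:
        raise ConfigError("band volumes must be >= 0")
    return ExpressionResult(
        gene=gene,
        treated_volume=float(treated_volume),
        control_volume=float(control_volume),
        ratio=float(treated_volume) / float(control_volume),
        detectable=True,
    )


def alpha_chain_ratio(alpha1_volume: float, alpha2_volume: float) -> AlphaChainRatio:
    """Alpha-1 over alpha-2 band volume (stoichiometric expectation: 2)."""
    if alpha2_volume <= 0:
        raise ConfigError("alpha-2 band volume must be > 0")
    if alpha1_volume < 0:
        raise ConfigError("band volumes must be >= 0")
    return AlphaChainRatio(
        alpha1_volume=float(alpha1_volume),
        alpha2_volume=float(alpha2_volume),
        ratio=float(alpha1_volume) / float(alpha2_volume),
    )


def identify_alpha_bands(
    bands: list[BandCall],
    max_gap_px: float = 25.0,
    mw_calibration: LadderCalibration | None = None,
) -> tuple[BandCall, BandCall]:
    """Find the collagen alpha-chain pair among SDS-PAGE band calls.

    The alpha chains appear as two close adjacent bands below a lone
    high-molecular-weight band. The rule: among bands sorted by migration
    distance, the unique adjacent pair with center gap <= ``max_gap_px``
    is the alpha pair; the slower (larger, smaller distance) band is
    alpha-1. No qualifying pair raises :class:`IdentificationError`; more
    than one (e.g. three equidistant close bands) raises
    :class:`AmbiguityError` rather than choosing silently. A
    molecular-weight calibration, when given, only annotates sizes.
    """
    discrete = sorted((b for b in bands if not b.is_smear), key=lambda b: b.center_px)
    if len(discrete) < 2:
        raise IdentificationError(
            f"need at least two discrete bands to find the alpha pair, got {len(discrete)}"
        )
    pairs = [
        (discrete[i], discrete[i + 1])
        for i in range(len(discrete) - 1)
        if discrete[i + 1].center_px - discrete[i].center_px <= max_gap_px
    ]
    if not pairs:
        raise IdentificationError(
            f"no adjacent band pair within {max_gap_px} px; cannot identify alpha chains"
        )
    if len(pairs) > 1:
        raise AmbiguityError(
            f"{len(pairs)} candidate close pairs; alpha-chain assignment is ambiguous"
        )
    alpha1, alpha2 = pairs[0]  # slower (smaller distance) first = alpha-1
    if mw_calibration is not None:
        alpha1.size_bp = float(mw_calibration.size_of(alpha1.center_px))
        alpha2.size_bp = float(mw_calibration.size_of(alpha2.center_px))
    return alpha1, alpha2
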