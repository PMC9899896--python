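"""Concentration-series design for in vitro genotoxicity assays.

Test concentrations follow a geometric ("half-log style") dilution series:
each point is ``spacing_factor`` times the previous one, top concentration
first.  The default factor 0.70711 (= 1/sqrt(2)) gives the 70.71 % spacing
used in TK6 screening designs (6 points for transcriptomic exposures, 10
points for the flow-cytometry assays).

Top concentrations are picked from a viability pre-screen: the highest tested
concentration retaining at least 40 % viability for the transcriptomic and
micronucleus assays, or 20 % viability for the multiplexed DNA-damage assay,
capped at 10 mM (10,000 uM).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "ConcentrationSeries",
    "build_series",
    "select_top_concentration",
    "VIABILITY_THRESHOLDS",
    "CONCENTRATION_CAP_UM",
]

#: Minimum % viability the top concentration must retain, per assay.
VIABILITY_THRESHOLDS: Mapping[str, float] = {
    "TGxDDI": 40.0,
    "MicroFlow": 40.0,
    "MultiFlow": 20.0,
}

#: Hard cap on the top concentration (uM); 10 mM.
CONCENTRATION_CAP_UM: float = 10_000.0


@dataclass(frozen=True)
class ConcentrationSeries:
    """A geometric concentration series, top concentration first.

    Attributes
    ----------
    top : float
        Top (highest) concentration in uM.
    n_points : int
        Number of concentrations.
    spacing_factor : float
        Ratio between successive concentrations, in (0, 1).
    concentrations : tuple of float
        ``top * spacing_factor**i`` for i = 0 .. n_points-1.
    """

    top: float
    n_points: int
    spacing_factor: float = 0.70711
    concentrations: tuple[float, ...] = field(default=(), compare=True)

    @property
    def lowest(self) -> float:
        """Lowest concentration, ``top * spacing_factor**(n_points - 1)``."""
        return self.concentrations[-1]

    def rounded(self, sig_figs: int = 4) -> tuple[float, ...]:
        """Concentrations rounded for display to ``sig_figs`` significant figures.

        Full precision is kept internally; rounding is presentation only.
        """
        import math

        out = []
        for c in self.concentrations:
            digits = sig_figs - 1 - math.floor(math.log10(abs(c)))
            out.append(round(c, digits))
        return tuple(out)


def build_series(
    top: float, n_points: int, spacing_factor: float = 0.70711
) -> ConcentrationSeries:
    """Build a geometric concentration series.

    Parameters
    ----------
    top : float
        Top concentration in uM; must be > 0.
    n_points : int
        Number of points; must be >= 1.
    spacing_factor : float
        Ratio of successive concentrations; must lie strictly in (0, 1).

    Returns
    -------
    ConcentrationSeries

    Examples
    --------
    >>> build_series(10000, 6).lowest  # doctest: +ELLIPSIS
    1767.9...
    """
    if top <= 0:
        raise ValueError(f"top concentration must be positive, got {top}")
    if n_points < 1:
        raise ValueError(f"n_points must be >= 1, got {n_points}")
    if not (0.0 < spacing_factor < 1.0):
        raise ValueError(
            f"spacing_factor must lie strictly in (0, 1), got {spacing_factor}"
        )
    concs = tuple(top * spacing_factor**i for i in range(n_points))
    return ConcentrationSeries(
        top=top,
        n_points=n_points,
        spacing_factor=spacing_factor,
        concentrations=concs,
    )


def select_top_concentration(
    viability_curve: Mapping[float, float] | Sequence[tuple[float, float]],
    assay: str,
    cap_uM: float = CONCENTRATION_CAP_UM,
) -> float:
    """Select the top concentration for an assay from a viability pre-screen.

    Returns the highest tested candidate concentration whose viability meets
    the assay threshold (>= 40 % for TGxDDI/MicroFlow, >= 20 % for MultiFlow),
    capped at ``cap_uM``.  If no candidate is cytotoxic (all viabilities meet
    the threshold) the cap itself is returned.  Viability between tested
    candidates is never interpolated — selection is restricted to tested
    concentrations.

    Parameters
    ----------
    viability_curve : mapping or sequence of (concentration, % viability)
        Tested candidate concentrations and their observed viability in [0, 100].
    assay : {"TGxDDI", "MicroFlow", "MultiFlow"}
    cap_uM : float
        Upper cap on the returned concentration (default 10,000 uM).
    """
    if assay not in VIABILITY_THRESHOLDS:
        raise ValueError(
            f"unknown assay {assay!r}; expected one of {sorted(VIABILITY_THRESHOLDS)}"
        )
    items = (
        list(viability_curve.items())
        if isinstance(viability_curve, Mapping)
        else list(viability_curve)
    )
    if not items:
        raise ValueError("viability curve is empty")
    for conc, viab in items:
        if not (0.0 <= viab <= 100.0):
            raise ValueError(f"viability {viab} at {conc} uM outside [0, 100]")

    threshold = VIABILITY_THRESHOLDS[assay]
    eligible = [c for c, v in items if v >= threshold and c <= cap_uM]
    if all(v >= threshold for _, v in items):
        # Non-cytotoxic over the whole tested range: test up to the cap.
        return cap_uM
    if not eligible:
        raise ValueError(
            f"no tested concentration retains >= {threshold}% viability for {assay}"
        )
    return max(eligible)
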