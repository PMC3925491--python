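"""Segment-wise river/aquifer exchange fluxes along a bank polyline.

The exchange through a bank segment follows Darcy's law, weighted by the
angle between groundwater flow and river flow:

    Qe = 86400 * K * i * A * sin(D)        [m3/day per m of bank]

where K is the aquifer permeability (m/s), i the piezometric gradient
(dimensionless, from the piezometric TIN slope), A the saturated exchange
cross-section thickness (m, groundwater head minus riverbed elevation,
clamped at 0) and D the angle (degrees) between the groundwater flow
azimuth and the river flow azimuth, normalized to (−180, 180].  The 86400
factor converts m3/s to m3/day, the scale at which these fluxes are legible.

Sign convention: positive Qe means the aquifer feeds the river (gaining
reach), negative means the river recharges the aquifer (losing reach); the
sign is carried entirely by sin(D).

Per zone, segment fluxes aggregate to Qf = sum(Qe * L) separately for each
sign, and unit flows Qu = Qf / (L / 1000) express the flux per kilometre of
bank.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import RivaqError, UndefinedFlowDirectionError
from . import tin

SECONDS_PER_DAY = 86400.0

DIRECTION_GAINING = "aquifer_to_river"
DIRECTION_LOSING = "river_to_aquifer"
DIRECTION_NONE = "none"


@dataclass
class BankSegment:
    """One segment of the bank polyline with its hydraulic attributes.

    ``gw_head``, ``i`` and the two aspects may be left ``None`` when the
    segment is to be filled in from the TINs by
    :func:`run_exchange_diagnosis`.
    """

    segment_id: str
    start: tuple[float, float]
    end: tuple[float, float]
    zone: str
    bank: str = "left"
    kp_range: tuple[float, float] | None = None
    K: float = 1e-3
    riverbed_z: float = 0.0
    gw_head: float | None = None
    i: float | None = None
    aspect_piezo: float | None = None
    aspect_river: float | None = None

    @property
    def L(self) -> float:
        return math.dist(self.start, self.end)

    @property
    def midpoint(self) -> tuple[float, float]:
        return (
            (self.start[0] + self.end[0]) / 2.0,
            (self.start[1] + self.end[1]) / 2.0,
        )


@dataclass(frozen=True)
class ExchangeEstimate:
    segment_id: str
    A: float
    D: float  # NaN when undefined
    Qe: float  # m3/day per m of bank
    QeL: float  # m3/day for the whole segment
    direction: str


@dataclass
class ZoneSummary:
    zone: str
    kp_range: tuple[float, float] | None = None
    Qf_pos: float = 0.0
    Qf_neg: float = 0.0
    L_pos: float = 0.0
    L_neg: float = 0.0
    n_segments: int = 0

    @property
    def Qu_pos(self) -> int:
        return unit_flow(self.Qf_pos, self.L_pos) if self.L_pos > 0 else 0

    @property
    def Qu_neg(self) -> int:
        return unit_flow(self.Qf_neg, self.L_neg) if self.L_neg > 0 else 0


def angle_D(aspect_piezo: float, aspect_river: float) -> float:
    """Angle between groundwater and river flow, normalized to (−180, 180]."""
    if aspect_piezo is None or aspect_river is None or \
            math.isnan(aspect_piezo) or math.isnan(aspect_river):
        raise UndefinedFlowDirectionError(
            "undefined flow direction: flat triangle has no aspect"
        )
    d = (aspect_piezo - aspect_river) % 360.0
    if d > 180.0:
        d -= 360.0
    return d


def cross_section(gw_head: float, riverbed_z: float) -> float:
    """Saturated exchange thickness A = max(head − riverbed, 0) in metres."""
    return max(gw_head - riverbed_z, 0.0)


def segment_qe(K: float, i: float, A: float, D: float | None) -> float:
    """Darcy flux per metre of bank, Qe = 86400 K i A sin(D), in m3/day/m.

    ``D = None`` (or NaN) means the groundwater flow direction is undefined
    (flat piezometric triangle); such segments exchange nothing.
    """
    if K <= 0:
        raise RivaqError(f"permeability must be positive, got {K}")
    if i < 0 or A < 0:
        raise RivaqError("gradient and cross-section must be non-negative")
    if D is None or math.isnan(D):
        return 0.0
    return SECONDS_PER_DAY * K * i * A * math.sin(math.radians(D))


def estimate_direction(Qe: float) -> str:
    if Qe > 0:
        return DIRECTION_GAINING
    if Qe < 0:
        return DIRECTION_LOSING
    return DIRECTION_NONE


def unit_flow(Qf: float, L: float) -> int:
    """Unit flow Qu = Qf / (L/1000) in m3/day/km, rounded half away from zero."""
    if L <= 0:
        raise RivaqError("zero-length zone")
    qu = Qf / (L / 1000.0)
    return int(math.copysign(math.floor(abs(qu) + 0.5), qu))


def zone_qf(
    estimates: Iterable[ExchangeEstimate],
    segments: Iterable[BankSegment],
) -> list[ZoneSummary]:
    """Aggregate per-segment fluxes Qe*L into per-zone, per-sign totals Qf.

    Gaining and losing sub-reaches of one zone are accumulated separately
    so that Qf_pos >= 0 >= Qf_neg always holds.
    """
    seg_by_id = {s.segment_id: s for s in segments}
    zones: dict[str, ZoneSummary] = {}
    for est in estimates:
        seg = seg_by_id.get(est.segment_id)
        if seg is None:
            raise RivaqError(f"estimate/segment mismatch: {est.segment_id!r}")
        summ = zones.setdefault(seg.zone, ZoneSummary(seg.zone, seg.kp_range))
        summ.n_segments += 1
        if seg.kp_range is not None and summ.kp_range is not None:
            lo = min(summ.kp_range[0], seg.kp_range[0])
            hi = max(summ.kp_range[1], seg.kp_range[1])
            summ.kp_range = (lo, hi)
        if est.QeL > 0:
            summ.Qf_pos += est.QeL
            summ.L_pos += seg.L
        elif est.QeL < 0:
            summ.Qf_neg += est.QeL
            summ.L_neg += seg.L
    return [zones[z] for z in sorted(zones)]


def segment_estimate(seg: BankSegment) -> ExchangeEstimate:
    """Darcy chain for one fully attributed segment."""
    A = cross_section(seg.gw_head, seg.riverbed_z)
    try:
        D = angle_D(seg.aspect_piezo, seg.aspect_river)
    except UndefinedFlowDirectionError:
        D = math.nan
    Qe = segment_qe(seg.K, seg.i, A, D)
    return ExchangeEstimate(
        seg.segment_id, A, D, Qe, Qe * seg.L, estimate_direction(Qe)
    )


def run_exchange_diagnosis(
    piezo: "tin.TriangulatedSurface",
    river: "tin.TriangulatedSurface",
    segments: Sequence[BankSegment],
) -> tuple[list[ExchangeEstimate], list[ZoneSummary]]:
    """Full chain: sample TINs -> D -> A -> Qe -> Qf per zone.

    The hydraulic gradient i, groundwater flow aspect and groundwater head
    are read from the piezometric TIN along each segment; the river flow
    aspect comes from the river-stage TIN.  Segment-supplied values
    (``gw_head``, ``i``, aspects) take precedence when present, so partial
    field knowledge can override the surfaces.
    """
    estimates = []
    for seg in segments:
        try:
            ap = tin.sample_segment(piezo, (seg.start, seg.end))
            ar = tin.sample_segment(river, (seg.start, seg.end))
        except RivaqError as exc:
            raise type(exc)(f"segment {seg.segment_id!r}: {exc}") from exc
        if seg.i is None:
            seg.i = ap.slope
        if seg.aspect_piezo is None:
            seg.aspect_piezo = ap.aspect if ap.defined_aspect else math.nan
        if seg.aspect_river is None:
            seg.aspect_river = ar.aspect if ar.defined_aspect else math.nan
        if seg.gw_head is None:
            # exact plane interpolation at the midpoint, not the triangle mean
            seg.gw_head = piezo.elevation_at(*seg.midpoint)
        estimates.append(segment_estimate(seg))
    return estimates, zone_qf(estimates, segments)


def sector_totals(summaries: Iterable[ZoneSummary]) -> ZoneSummary:
    """Whole-sector totals across zones (the Total row of a synthesis table)."""
    total = ZoneSummary("TOTAL")
    for s in summaries:
        total.Qf_pos += s.Qf_pos
        total.Qf_neg += s.Qf_neg
        total.L_pos += s.L_pos
        total.L_neg += s.L_neg
        total.n_segments += s.n_segments
    return total
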