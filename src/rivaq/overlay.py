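"""Overlay of the hydraulic, macrophyte and invertebrate exchange maps.

The three indicators live on different supports (bank polyline zones,
wetland sites, fauna sections), so they are first aligned on a common
partition of kilometric-point (KP) intervals per bank.  Each aligned zone
record is then reduced to per-metric exchange signs — gain (aquifer feeds
river / groundwater influence), loss (river feeds aquifer / no groundwater
influence) or none — and a convergence verdict issued:

* convergent   — all present metrics agree on gain or loss,
* partial      — metrics agree but at least one is none/absent,
* divergent    — gain and loss both claimed,
* incomparable — fewer than two metrics present.

Cross-metric correlations use ordinary least squares on zone pairs, with
qualitative classes encoded ordinally (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import RivaqError

SIGN_GAIN = "gain"
SIGN_LOSS = "loss"
SIGN_NONE = "none"

#: default reduction of macrophyte groundwater-influence classes to a sign
MACRO_SIGN = {
    "null": SIGN_LOSS,
    "low": SIGN_NONE,
    "intermediate": SIGN_GAIN,
    "high": SIGN_GAIN,
}

#: default reduction of invertebrate section categories to a sign
INVERT_SIGN = {"none": SIGN_LOSS, "mixed": SIGN_NONE, "upwelling": SIGN_GAIN}

#: default ordinal encoding of qualitative classes for correlations
ORDINAL_ENCODING = {
    "null": 0, "none": 0,
    "low": 1, "weak": 1, "mixed": 1,
    "intermediate": 2, "medium": 2,
    "high": 3, "upwelling": 3,
}


@dataclass
class ZoneRecord:
    zone: str
    kp_range: tuple[float, float]
    bank: str = "left"
    reach_type: str = ""
    Qf: float | None = None
    Qu: float | None = None
    macrophyte_class: str | None = None  # groundwater-influence class
    trophic_class: str | None = None
    invertebrate_class: str | None = None  # section category

    @property
    def n_metrics(self) -> int:
        return sum(
            v is not None
            for v in (self.Qu if self.Qu is not None else self.Qf,
                      self.macrophyte_class, self.invertebrate_class)
        )


@dataclass(frozen=True)
class ConvergenceVerdict:
    zone: str
    verdict: str
    rationale: str


@dataclass(frozen=True)
class CorrelationResult:
    pair: tuple[str, str]
    n: int
    R2: float
    p: float
    slope: float


def _check_partition(partition):
    by_bank: dict[str, list[tuple[float, float]]] = {}
    for bank, lo, hi in partition:
        lo, hi = min(lo, hi), max(lo, hi)
        for plo, phi in by_bank.get(bank, []):
            if lo < phi and plo < hi:
                raise RivaqError(
                    f"ambiguous partition: [{lo}, {hi}] overlaps [{plo}, {phi}] "
                    f"on bank {bank!r}"
                )
        by_bank.setdefault(bank, []).append((lo, hi))


def build_zone_table(
    partition: list[tuple[str, float, float]],
    hydraulic: list | None = None,
    macro: list[tuple[str, float, str, str]] | None = None,
    invert: list | None = None,
) -> tuple[list[ZoneRecord], list[str]]:
    """Align the three metric sets on a (bank, kp_lo, kp_hi) partition.

    ``hydraulic`` holds zone summaries with ``kp_range`` plus signed
    ``Qf``/``Qu`` totals (a net value is used: Qf_pos + Qf_neg);
    ``macro`` rows are (bank, kp, influence_class, trophic_class) per
    wetland site; ``invert`` holds section classifications with
    ``kp_range``.  Each metric lands in the interval containing its KP
    midpoint; metrics matching no interval are returned as unassigned
    notes.  Records are ordered upstream -> downstream (decreasing KP).
    """
    _check_partition(partition)
    records = []
    for i, (bank, lo, hi) in enumerate(partition):
        lo, hi = min(lo, hi), max(lo, hi)
        records.append(ZoneRecord(zone=f"{hi:g}_{lo:g}:{bank}",
                                  kp_range=(lo, hi), bank=bank))
    unassigned: list[str] = []

    def _find(bank, kp):
        for rec in records:
            if rec.bank == bank and rec.kp_range[0] <= kp <= rec.kp_range[1]:
                return rec
        return None

    for summ in hydraulic or []:
        if summ.kp_range is None:
            unassigned.append(f"hydraulic zone {summ.zone}: no KP range")
            continue
        mid = sum(summ.kp_range) / 2.0
        rec = _find(getattr(summ, "bank", "left"), mid)
        if rec is None:
            unassigned.append(f"hydraulic zone {summ.zone} at KP {mid:g}")
            continue
        qf = summ.Qf_pos + summ.Qf_neg
        rec.Qf = (rec.Qf or 0.0) + qf
        L = summ.L_pos + summ.L_neg
        if L > 0:
            from .exchange import unit_flow

            rec.Qu = unit_flow(rec.Qf, L)
    for bank, kp, infl, troph in macro or []:
        rec = _find(bank, kp)
        if rec is None:
            unassigned.append(f"macrophyte site at KP {kp:g} ({bank})")
            continue
        # keep the strongest influence class seen in the zone
        order = ["null", "low", "intermediate", "high"]
        if rec.macrophyte_class is None or order.index(infl) > order.index(
            rec.macrophyte_class
        ):
            rec.macrophyte_class = infl
            rec.trophic_class = troph
    for sec in invert or []:
        mid = sum(sec.kp_range) / 2.0
        rec = _find(getattr(sec, "bank", "left"), mid)
        if rec is None:
            unassigned.append(f"invertebrate section {sec.section_id} at KP {mid:g}")
            continue
        rec.invertebrate_class = sec.category
    records.sort(key=lambda r: (r.bank, -r.kp_range[1]))
    return records, unassigned


def metric_signs(
    record: ZoneRecord,
    macro_sign: dict[str, str] | None = None,
    invert_sign: dict[str, str] | None = None,
) -> dict[str, str]:
    """Reduce each present metric of a record to gain/loss/none."""
    macro_sign = macro_sign or MACRO_SIGN
    invert_sign = invert_sign or INVERT_SIGN
    signs = {}
    q = record.Qu if record.Qu is not None else record.Qf
    if q is not None:
        signs["hydraulic"] = SIGN_GAIN if q > 0 else SIGN_LOSS if q < 0 else SIGN_NONE
    if record.macrophyte_class is not None:
        signs["macrophyte"] = macro_sign[record.macrophyte_class]
    if record.invertebrate_class is not None:
        signs["invertebrate"] = invert_sign[record.invertebrate_class]
    return signs


def verdict(record: ZoneRecord, **kwargs) -> ConvergenceVerdict:
    """Convergence verdict for one aligned zone record."""
    signs = metric_signs(record, **kwargs)
    detail = ", ".join(f"{m}={s}" for m, s in sorted(signs.items()))
    if len(signs) < 2:
        return ConvergenceVerdict(record.zone, "incomparable",
                                  f"fewer than 2 metrics ({detail or 'none'})")
    directed = {s for s in signs.values() if s != SIGN_NONE}
    if SIGN_GAIN in directed and SIGN_LOSS in directed:
        return ConvergenceVerdict(record.zone, "divergent", detail)
    if len(directed) == 1 and all(s != SIGN_NONE for s in signs.values()):
        return ConvergenceVerdict(record.zone, "convergent", detail)
    return ConvergenceVerdict(record.zone, "partial", detail)


def encode_ordinal(value, encoding: dict | None = None) -> float:
    if value is None:
        return float("nan")
    if isinstance(value, (int, float, np.floating, np.integer)):
        return float(value)
    enc = encoding or ORDINAL_ENCODING
    key = str(value).lower()
    if key not in enc:
        raise RivaqError(f"no ordinal encoding for class {value!r}")
    return float(enc[key])


def correlate(
    x, y, pair: tuple[str, str] = ("x", "y"), encoding: dict | None = None
) -> CorrelationResult:
    """OLS correlation between two zone metrics.

    Qualitative classes are ordinally encoded; pairs with a missing side
    are dropped.  R2 is the squared Pearson correlation and p the
    two-sided slope t-test, as given by :func:`scipy.stats.linregress`.
    """
    xv = np.array([encode_ordinal(v, encoding) for v in x])
    yv = np.array([encode_ordinal(v, encoding) for v in y])
    mask = ~(np.isnan(xv) | np.isnan(yv))
    xv, yv = xv[mask], yv[mask]
    if xv.size < 3:
        raise RivaqError(f"need >= 3 complete zone pairs, got {xv.size}")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise RivaqError("degenerate correlation: zero variance")
    res = stats.linregress(xv, yv)
    return CorrelationResult(pair, int(xv.size), float(res.rvalue**2),
                             float(res.pvalue), float(res.slope))
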