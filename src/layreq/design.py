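"""Trial-design bookkeeping for supplemental trace-mineral dose-response trials.

A design is a completely randomized layout: one unsupplemented control plus a
grid of (source × added level) treatments, each replicated as groups of birds
followed over consecutive periods.  Doses are tracked on three scales:

* ``supplement_rate`` — mg of the additive product per kg of diet;
* ``nominal_added_mn`` — mg of elemental Mn per kg contributed by the additive,
  i.e. ``supplement_rate × mn_fraction``;
* ``analyzed_total_mn`` — mg/kg total Mn measured in the mixed diet (optional;
  when absent, ``basal_mn + nominal_added_mn`` is the best available total).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

from .errors import InvalidDesignError

#: Canonical source labels; "none" marks the unsupplemented control.
SOURCES = ("none", "oxide", "sulphate", "organic")

#: Tolerance (mg/kg) for agreement between a printed nominal added level and
#: rate × fraction arithmetic.  Inclusion rates are themselves rounded to
#: whole mg/kg of additive, so the worst case slightly exceeds 0.5 mg/kg of
#: Mn (e.g. a 130 mg/kg rate of a 69.62 % additive gives 90.51 for a printed
#: nominal of 90).
NOMINAL_TOL = 0.6


@dataclass(frozen=True)
class Treatment:
    """One diet: a source, its inclusion rate and the resulting Mn doses."""

    id: int
    source: str
    supplement_rate: float          # mg additive / kg diet
    mn_fraction: Optional[float]    # mass fraction Mn in the additive
    nominal_added_mn: float         # mg Mn / kg diet
    analyzed_total_mn: Optional[float] = None

    def total_mn(self, basal_mn: float, scale: str = "analyzed") -> float:
        """Total dietary Mn (mg/kg) on the requested scale.

        ``scale="analyzed"`` uses the measured diet concentration when present
        and falls back to ``basal + nominal``; ``scale="nominal"`` always uses
        ``basal + nominal``.
        """
        if scale == "analyzed" and self.analyzed_total_mn is not None:
            return self.analyzed_total_mn
        return basal_mn + self.nominal_added_mn


@dataclass(frozen=True)
class TrialDesign:
    """Full layout of a dose-response trial."""

    treatments: tuple[Treatment, ...]
    basal_mn: float                 # mg/kg in the unsupplemented diet
    n_replicates: int
    birds_per_replicate: int
    n_periods: int
    period_days: int

    @property
    def sources(self) -> tuple[str, ...]:
        """Supplemented sources present, in first-appearance order."""
        seen: list[str] = []
        for t in self.treatments:
            if t.source != "none" and t.source not in seen:
                seen.append(t.source)
        return tuple(seen)

    @property
    def control(self) -> Treatment:
        for t in self.treatments:
            if t.source == "none":
                return t
        raise InvalidDesignError("design has no control treatment")

    def arm(self, source: str) -> tuple[Treatment, ...]:
        """Control plus the treatments of one source, in dose order."""
        arm = [self.control] + sorted(
            (t for t in self.treatments if t.source == source),
            key=lambda t: t.nominal_added_mn,
        )
        return tuple(arm)

    def doses(self, treatments: Sequence[Treatment], scale: str = "analyzed") -> list[float]:
        return [t.total_mn(self.basal_mn, scale) for t in treatments]

    def to_json(self, path) -> None:
        payload = {
            "basal_mn": self.basal_mn,
            "n_replicates": self.n_replicates,
            "birds_per_replicate": self.birds_per_replicate,
            "n_periods": self.n_periods,
            "period_days": self.period_days,
            "treatments": [asdict(t) for t in self.treatments],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


def make_design(config: dict) -> TrialDesign:
    """Build and validate a :class:`TrialDesign` from a plain-dict config.

    The config carries ``basal_mn``, replication fields and a ``treatments``
    list of dicts with ``source``, ``supplement_rate``, ``mn_fraction`` and
    optionally ``nominal_added_mn`` (printed value, checked against the
    rate × fraction arithmetic to ±0.5 mg/kg) and ``analyzed_total_mn``.

    Raises
    ------
    InvalidDesignError
        On negative rates, fractions outside (0, 1], a missing/invalid
        control, printed nominal levels inconsistent with the arithmetic, or
        analyzed totals below the basal concentration.
    """
    basal = float(config["basal_mn"])
    if basal < 0:
        raise InvalidDesignError("basal_mn must be >= 0")

    treatments: list[Treatment] = []
    for i, row in enumerate(config["treatments"], start=1):
        source = row["source"]
        if source not in SOURCES:
            raise InvalidDesignError(f"unknown source {source!r}")
        rate = float(row.get("supplement_rate", 0.0))
        if rate < 0:
            raise InvalidDesignError(f"treatment {i}: negative supplement_rate {rate}")
        frac = row.get("mn_fraction")
        if source == "none":
            if rate != 0:
                raise InvalidDesignError("control treatment must have supplement_rate 0")
            nominal = 0.0
        else:
            if frac is None or not (0.0 < float(frac) <= 1.0):
                raise InvalidDesignError(
                    f"treatment {i}: mn_fraction must lie in (0, 1], got {frac!r}"
                )
            frac = float(frac)
            nominal = rate * frac
            stated = row.get("nominal_added_mn")
            if stated is not None:
                if abs(float(stated) - nominal) > NOMINAL_TOL:
                    raise InvalidDesignError(
                        f"treatment {i}: stated nominal_added_mn {stated} differs from "
                        f"rate × fraction = {nominal:.2f} by more than {NOMINAL_TOL} mg/kg"
                    )
                nominal = float(stated)
        analyzed = row.get("analyzed_total_mn")
        if analyzed is not None:
            analyzed = float(analyzed)
            if analyzed < basal:
                raise InvalidDesignError(
                    f"treatment {i}: analyzed_total_mn {analyzed} < basal_mn {basal}"
                )
        treatments.append(
            Treatment(
                id=i,
                source=source,
                supplement_rate=rate,
                mn_fraction=None if source == "none" else frac,
                nominal_added_mn=nominal,
                analyzed_total_mn=analyzed,
            )
        )

    if sum(1 for t in treatments if t.source == "none") != 1:
        raise InvalidDesignError("design must contain exactly one control treatment")

    return TrialDesign(
        treatments=tuple(treatments),
        basal_mn=basal,
        n_replicates=int(config.get("n_replicates", 6)),
        birds_per_replicate=int(config.get("birds_per_replicate", 12)),
        n_periods=int(config.get("n_periods", 3)),
        period_days=int(config.get("period_days", 28)),
    )


def load_design(path) -> TrialDesign:
    """Read a design.json previously written by :meth:`TrialDesign.to_json`."""
    with open(path, encoding="utf-8") as fh:
        return make_design(json.load(fh))
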