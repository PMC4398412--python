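"""Census-table projection and creole-emergence classification.

Reads demographic tables with counts of Free Whites (Europeans), Free
Colored (Mulattos) and Slaves (Bozals), projects each territory into the
(x, y) demographic plane, and classifies it against a transition stripe:
above the stripe the model predicts a creole emerged, below it the
European language prevailed, and on the stripe the verdict is uncertain.

No historical census numbers are bundled; :func:`synthesize_census`
generates labelled synthetic tables emulating the observed clustering
(creole territories at high Black fraction, non-creole ones at low) for
testing and demonstration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    EmptyEvaluationError,
    EmptyInputError,
    GenerationError,
    SchemaError,
    UnclassifiableError,
)
from .phase import DemographicPoint, TransitionStripe, point_to_counts

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("territory", "n_white", "n_free_colored", "n_slave")
OPTIONAL_COLUMNS = ("subdivision", "year", "creole_observed")

#: Common header spellings accepted out of the box (alias -> canonical).
DEFAULT_ALIASES = {
    "state": "territory",
    "county": "subdivision",
    "parish": "subdivision",
    "free_whites": "n_white",
    "whites": "n_white",
    "europeans": "n_white",
    "free_colored": "n_free_colored",
    "free_blacks": "n_free_colored",
    "mulattos": "n_free_colored",
    "slaves": "n_slave",
    "bozals": "n_slave",
    "creole": "creole_observed",
}

CREOLE_PREDICTED = "creole_predicted"
NO_CREOLE_PREDICTED = "no_creole_predicted"
UNCERTAIN = "uncertain"


@dataclass(frozen=True)
class CensusRecord:
    """One census row: a territory (or subdivision) with group counts."""

    territory: str
    n_white: int
    n_free_colored: int
    n_slave: int
    subdivision: str | None = None
    year: int | None = None
    creole_observed: bool | None = None

    def __post_init__(self) -> None:
        if min(self.n_white, self.n_free_colored, self.n_slave) < 0:
            raise ValueError("census counts must be non-negative")

    @property
    def label(self) -> str:
        return (
            f"{self.territory}/{self.subdivision}"
            if self.subdivision
            else self.territory
        )


@dataclass(frozen=True)
class Classification:
    """Verdict for one record against the transition stripe."""

    record: CensusRecord
    point: DemographicPoint
    verdict: str  # creole_predicted | no_creole_predicted | uncertain
    distance_to_mid: float  # signed: y minus the mid-curve y at this x


def read_census_csv(
    path: str | Path, aliases: dict[str, str] | None = None
) -> list[CensusRecord]:
    """Load and validate a census CSV.

    Headers are lower-cased and mapped through the alias table (user
    aliases extend :data:`DEFAULT_ALIASES`).  Rows with negative or
    non-numeric counts are rejected with a logged row-level diagnostic.
    Lines starting with ``#`` are treated as comments.
    """
    alias_map = dict(DEFAULT_ALIASES)
    if aliases:
        alias_map.update({k.strip().lower(): v for k, v in aliases.items()})
    df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    df.columns = [
        alias_map.get(c.strip().lower(), c.strip().lower()) for c in df.columns
    ]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if df.empty:
        raise EmptyInputError(f"{path}: no census rows")

    records: list[CensusRecord] = []
    for idx, row in df.iterrows():
        try:
            counts = {
                c: int(row[c]) for c in ("n_white", "n_free_colored", "n_slave")
            }
        except (TypeError, ValueError):
            logger.warning("%s row %d: non-numeric count, row rejected", path, idx)
            continue
        if min(counts.values()) < 0:
            logger.warning("%s row %d: negative count, row rejected", path, idx)
            continue
        creole = row.get("creole_observed")
        if creole is not None and not pd.isna(creole):
            if isinstance(creole, str):
                creole = creole.strip().lower() in ("1", "true", "yes", "y")
            else:
                creole = bool(creole)
        else:
            creole = None
        year = row.get("year")
        records.append(
            CensusRecord(
                territory=str(row["territory"]),
                subdivision=(
                    None
                    if pd.isna(row.get("subdivision", np.nan))
                    else str(row["subdivision"])
                ),
                year=None if pd.isna(year) else int(year),
                creole_observed=creole,
                **counts,
            )
        )
    return records


def to_point(record: CensusRecord) -> DemographicPoint:
    """Project a record to x = M/(M+B), y = (M+B)/(Eu+M+B)."""
    black = record.n_free_colored + record.n_slave
    if black < 1:
        raise UnclassifiableError(
            f"{record.label}: no Black population, (x, y) undefined"
        )
    total = record.n_white + black
    return DemographicPoint(x=record.n_free_colored / black, y=black / total)


def classify(
    point: DemographicPoint, stripe: TransitionStripe, record: CensusRecord | None = None
) -> Classification:
    """Three-way verdict: above the stripe, below it, or inside it.

    The boundary curves are inclusive: a point exactly on the lower or
    upper curve is uncertain.
    """
    lower = stripe.lower_at(point.x)
    upper = stripe.upper_at(point.x)
    mid = stripe.mid_at(point.x)
    if point.y > upper:
        verdict = CREOLE_PREDICTED
    elif point.y < lower:
        verdict = NO_CREOLE_PREDICTED
    else:
        verdict = UNCERTAIN
    return Classification(
        record=record,
        point=point,
        verdict=verdict,
        distance_to_mid=point.y - mid,
    )


def classify_records(
    records: list[CensusRecord], stripe: TransitionStripe
) -> list[Classification]:
    """Classify every classifiable record; zero-Black rows are skipped."""
    out = []
    for rec in records:
        try:
            point = to_point(rec)
        except UnclassifiableError as exc:
            logger.warning("skipping record: %s", exc)
            continue
        out.append(classify(point, stripe, record=rec))
    return out


@dataclass(frozen=True)
class PredictionSummary:
    """Confusion counts over records with an observed-creole label."""

    n_correct: int
    n_incorrect: int
    n_uncertain: int
    accuracy: float  # over decided (non-uncertain) labelled records
    borderline: tuple[Classification, ...]  # ordered by |distance to mid curve|


def evaluate_predictions(
    classifications: list[Classification],
) -> PredictionSummary:
    """Compare verdicts with observed-creole labels.

    Uncertain verdicts are excluded from the accuracy denominator and
    listed as borderline, ordered by distance to the mid curve.
    """
    labelled = [
        c
        for c in classifications
        if c.record is not None and c.record.creole_observed is not None
    ]
    if not labelled:
        raise EmptyEvaluationError("no record carries an observed-creole label")
    correct = incorrect = uncertain = 0
    for c in labelled:
        if c.verdict == UNCERTAIN:
            uncertain += 1
        else:
            predicted = c.verdict == CREOLE_PREDICTED
            if predicted == c.record.creole_observed:
                correct += 1
            else:
                incorrect += 1
    decided = correct + incorrect
    borderline = tuple(
        sorted(
            (c for c in labelled if c.verdict == UNCERTAIN),
            key=lambda c: abs(c.distance_to_mid),
        )
    )
    return PredictionSummary(
        n_correct=correct,
        n_incorrect=incorrect,
        n_uncertain=uncertain,
        accuracy=correct / decided if decided else float("nan"),
        borderline=borderline,
    )


def classifications_to_frame(classifications: list[Classification]) -> pd.DataFrame:
    """Tabular output: territory, counts, x, y, verdict, distance to mid."""
    rows = []
    for c in classifications:
        rec = c.record
        rows.append(
            {
                "territory": rec.territory if rec else "",
                "subdivision": (rec.subdivision or "") if rec else "",
                "x": c.point.x,
                "y": c.point.y,
                "verdict": c.verdict,
                "distance_to_mid_curve": c.distance_to_mid,
            }
        )
    return pd.DataFrame(rows)


def synthesize_census(
    n_creole_like: int,
    n_noncreole_like: int,
    margin: float,
    stripe: TransitionStripe,
    seed: int,
) -> list[CensusRecord]:
    """Generate labelled synthetic census records around a stripe.

    Creole-like records are placed at least ``margin`` above the upper
    curve (label True), non-creole-like at least ``margin`` below the lower
    curve (label False), mirroring the empirical clustering of creole
    territories at high Black fraction.  Totals are drawn log-uniformly
    over 10^2–10^6 and converted to integer counts consistent with (x, y);
    draws whose integer rounding would cross the margin are rejected.
    """
    if margin <= 0:
        raise ValueError("margin must be positive")
    rng = np.random.default_rng(seed)
    ok = ~np.isnan(stripe.y_lower) & ~np.isnan(stripe.y_upper)
    if not ok.any():
        raise GenerationError("stripe has no defined x range")
    x_lo, x_hi = float(stripe.xs[ok].min()), float(stripe.xs[ok].max())

    records: list[CensusRecord] = []
    for want_creole, count in ((True, n_creole_like), (False, n_noncreole_like)):
        made = 0
        attempts = 0
        while made < count:
            attempts += 1
            if attempts > 200 * max(count, 1):
                raise GenerationError(
                    f"margin {margin} leaves no room "
                    f"{'above' if want_creole else 'below'} the stripe"
                )
            x = float(rng.uniform(x_lo, x_hi))
            if want_creole:
                y_min = stripe.upper_at(x) + margin
                if y_min >= 0.999:
                    continue
                y = float(rng.uniform(y_min, min(0.999, y_min + 0.25)))
            else:
                y_max = stripe.lower_at(x) - margin
                if y_max <= 0.02:
                    continue
                y = float(rng.uniform(max(0.02, y_max - 0.25), y_max))
            total = int(round(10 ** rng.uniform(2.5, 6.0)))
            try:
                n_eu, n_m, n_b = point_to_counts(
                    DemographicPoint(x=x, y=y), total
                )
            except Exception:
                continue
            rec = CensusRecord(
                territory=f"SYN-{'C' if want_creole else 'N'}{made + 1:02d}",
                n_white=n_eu,
                n_free_colored=n_m,
                n_slave=n_b,
                year=1790,
                creole_observed=want_creole,
            )
            # integer rounding must not push the point across the stripe
            pt = to_point(rec)
            if want_creole and pt.y <= stripe.upper_at(pt.x):
                continue
            if not want_creole and pt.y >= stripe.lower_at(pt.x):
                continue
            records.append(rec)
            made += 1
    return records


def write_census_csv(records: list[CensusRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "territory": [r.territory for r in records],
            "subdivision": [r.subdivision or "" for r in records],
            "year": [r.year for r in records],
            "n_white": [r.n_white for r in records],
            "n_free_colored": [r.n_free_colored for r in records],
            "n_slave": [r.n_slave for r in records],
            "creole_observed": [r.creole_observed for r in records],
        }
    ).to_csv(path, index=False)
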