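"""Molecular gut-content detection rates and community composition.

PCR-based gut-content screening assays field-collected predators for
prey-specific DNA. For each predator taxon three counts matter: individuals
collected, individuals successfully assayed (DNA extracted and tested), and
individuals scoring positive for the target band. The positive detection
rate is computed over *assayed* individuals,

    rate = 100 * n_positive / n_detected,

never over the collected count: extraction failures are reported separately
and a taxon with zero assayed individuals has an *undefined* rate, which is
distinct from a true 0%.

Community composition summaries (per-species and per-class percentages of
the collected totals) live here too, since they come from the same survey
table.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .errors import DegenerateDataError, InvalidInputError, UndefinedRateError

__all__ = [
    "DetectionRecord",
    "DetectionTable",
    "DetectionSummary",
    "CompositionSummary",
    "detection_rate",
    "summarize_detection",
    "community_composition",
    "binomial_ci",
]


@dataclass(frozen=True)
class DetectionRecord:
    """Per-taxon survey counts: collected >= detected (assayed) >= positive."""

    order: str
    family: str
    species: str
    n_collected: int
    n_detected: int
    n_positive: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_positive <= self.n_detected <= self.n_collected:
            raise InvalidInputError(
                f"{self.species}: require 0 <= positive <= detected <= collected, "
                f"got {self.n_positive}/{self.n_detected}/{self.n_collected}"
            )


@dataclass(frozen=True)
class DetectionTable:
    """A survey table of :class:`DetectionRecord` with unique species labels."""

    records: tuple[DetectionRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if not self.records:
            raise InvalidInputError("DetectionTable requires at least one record")
        species = [r.species for r in self.records]
        if len(set(species)) != len(species):
            dupes = {s for s in species if species.count(s) > 1}
            raise InvalidInputError(f"duplicate species labels: {sorted(dupes)}")


@dataclass(frozen=True)
class DetectionSummary:
    """Pooled and per-taxon positive detection rates for one survey table.

    ``per_taxon_rate`` maps species to a percent, or ``None`` where the taxon
    had zero assayed individuals (undefined, not 0%). ``extraction_failures``
    is collected minus detected, summed.
    """

    pooled_rate: float
    per_taxon_rate: Mapping[str, float | None]
    positive_taxa: tuple[str, ...]
    total_collected: int
    total_detected: int
    total_positive: int
    extraction_failures: int


@dataclass(frozen=True)
class CompositionSummary:
    """Per-species and per-class shares of a community count table.

    ``per_species``: (species, count, percent of grand total);
    ``per_class``: (class label, species count, individual count, percent).
    """

    per_species: tuple[tuple[str, int, float], ...]
    per_class: tuple[tuple[str, int, int, float], ...]
    grand_total: int


def detection_rate(record: DetectionRecord) -> float:
    """Positive detection percent: 100 * positive / detected.

    Raises :class:`UndefinedRateError` when no individuals were assayed.
    """
    if record.n_detected == 0:
        raise UndefinedRateError(
            f"{record.species}: no individuals assayed; rate undefined (not 0%)"
        )
    return 100.0 * record.n_positive / record.n_detected


def summarize_detection(table: DetectionTable) -> DetectionSummary:
    """Pool a detection table: overall rate, per-taxon rates, positive taxa.

    The pooled rate is ``100 * sum(positive) / sum(detected)``, which equals
    the detected-count-weighted mean of the per-taxon rates.
    """
    total_detected = sum(r.n_detected for r in table.records)
    if total_detected == 0:
        raise UndefinedRateError("no individuals assayed in the whole table")
    total_positive = sum(r.n_positive for r in table.records)
    total_collected = sum(r.n_collected for r in table.records)
    per_taxon: dict[str, float | None] = {
        r.species: (detection_rate(r) if r.n_detected > 0 else None)
        for r in table.records
    }
    positive = tuple(r.species for r in table.records if r.n_positive > 0)
    return DetectionSummary(
        pooled_rate=100.0 * total_positive / total_detected,
        per_taxon_rate=per_taxon,
        positive_taxa=positive,
        total_collected=total_collected,
        total_detected=total_detected,
        total_positive=total_positive,
        extraction_failures=total_collected - total_detected,
    )


def community_composition(
    counts: Iterable[tuple[str, str, int]]
) -> CompositionSummary:
    """Summarise a (class, species, count) table into percentage shares.

    Percentages are of the grand total of individuals; per-class rows also
    carry the number of species in the class.
    """
    rows = [(str(c), str(s), int(n)) for c, s, n in counts]
    if any(n < 0 for _, _, n in rows):
        raise InvalidInputError("counts must be non-negative")
    grand = sum(n for _, _, n in rows)
    if grand == 0:
        raise DegenerateDataError("all counts are zero")

    per_species = tuple((s, n, 100.0 * n / grand) for _, s, n in rows)
    by_class: dict[str, list[int]] = defaultdict(lambda: [0, 0])
    for c, _, n in rows:
        by_class[c][0] += 1
        by_class[c][1] += n
    per_class = tuple(
        (c, sp, ind, 100.0 * ind / grand) for c, (sp, ind) in by_class.items()
    )
    return CompositionSummary(
        per_species=per_species, per_class=per_class, grand_total=grand
    )


def binomial_ci(
    record: DetectionRecord, level: float = 0.95
) -> tuple[float, float]:
    """Exact Clopper-Pearson interval for the positivity proportion.

    Uses the beta-quantile form: lower = B(alpha/2; k, n-k+1),
    upper = B(1-alpha/2; k+1, n-k), with the conventional boundary values
    0 at k=0 and 1 at k=n. Returned on the proportion scale in [0, 1].
    """
    if not 0 < level < 1:
        raise InvalidInputError(f"level must be in (0, 1), got {level}")
    n, k = record.n_detected, record.n_positive
    if n == 0:
        raise UndefinedRateError("no individuals assayed; interval undefined")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper
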