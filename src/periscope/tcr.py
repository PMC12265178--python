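"""TCR repertoire diversity: Shannon index, quality filters, longitudinal deltas.

Clonality is summarized by the Shannon diversity index
``H = -sum_i p_i ln p_i`` over CDR3 read proportions (natural log, raw —
no evenness normalization).  Samples with zero diversity or fewer than
10 detected clones are flagged as low quality and excluded from
downstream analyses; a drop in H from baseline to early treatment
indicates clonal expansion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ClonotypeTable, SampleTable, ValidationError

__all__ = [
    "DiversityRecord",
    "MIN_CLONES",
    "shannon_diversity",
    "diversity_records",
    "apply_repertoire_filters",
    "diversity_delta",
]

log = logging.getLogger(__name__)

#: Repertoires with fewer detected clones are excluded as low quality.
MIN_CLONES = 10


@dataclass
class DiversityRecord:
    sample_id: str
    n_clones: int
    total_reads: int
    shannon: float
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if self.n_clones > 1 and self.shannon == 0:
            raise ValidationError(
                f"{self.sample_id}: H = 0 with {self.n_clones} clones is contradictory"
            )
        if self.n_clones == 1 and self.shannon != 0:
            raise ValidationError(f"{self.sample_id}: single clone must have H = 0")


def shannon_diversity(table: ClonotypeTable) -> float:
    """Shannon index over clone read proportions, natural log."""
    if table.n_clones == 0:
        raise ValidationError(f"sample {table.sample_id}: empty clonotype table")
    counts = table.clones["count"].to_numpy(dtype=float)
    return float(stats.entropy(counts))  # normalizes and uses ln


def diversity_records(tables: Iterable[ClonotypeTable]) -> list[DiversityRecord]:
    """Compute per-sample diversity; empty repertoires are excluded directly."""
    records = []
    for t in tables:
        if t.n_clones == 0:
            records.append(
                DiversityRecord(t.sample_id, 0, 0, 0.0, True, "empty repertoire")
            )
            continue
        records.append(
            DiversityRecord(t.sample_id, t.n_clones, t.total_reads, shannon_diversity(t))
        )
    return apply_repertoire_filters(records)


def apply_repertoire_filters(records: Sequence[DiversityRecord]) -> list[DiversityRecord]:
    """Flag low-quality repertoires: H = 0 or fewer than ``MIN_CLONES`` clones.

    The clone-count boundary is strict (exactly 10 clones is retained).
    """
    out = []
    for r in records:
        reasons = []
        if r.shannon == 0:
            reasons.append("zero Shannon diversity")
        if r.n_clones < MIN_CLONES:
            reasons.append(f"fewer than {MIN_CLONES} clones")
        out.append(
            DiversityRecord(
                r.sample_id,
                r.n_clones,
                r.total_reads,
                r.shannon,
                excluded=bool(reasons),
                exclusion_reason="; ".join(reasons),
            )
        )
    return out


def records_frame(records: Sequence[DiversityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "n_clones": r.n_clones,
                "total_reads": r.total_reads,
                "shannon": r.shannon,
                "excluded": r.excluded,
                "exclusion_reason": r.exclusion_reason,
            }
            for r in records
        ]
    )


def diversity_delta(
    records: Sequence[DiversityRecord],
    metadata: SampleTable,
    from_tp: str = "Baseline",
    to_tp: str = "EarlyTreatment",
) -> pd.DataFrame:
    """Per-patient change ``H(to) - H(from)``; negative means clonal expansion.

    Patients missing a retained repertoire at either timepoint are
    omitted with a log entry.
    """
    retained = {r.sample_id: r.shannon for r in records if not r.excluded}
    meta = metadata.frame
    rows = []
    for pid, grp in meta.groupby("patient_id", sort=True):
        by_tp = grp.set_index("timepoint")["sample_id"].to_dict()
        sid_from, sid_to = by_tp.get(from_tp), by_tp.get(to_tp)
        if sid_from not in retained or sid_to not in retained:
            log.info("patient %s omitted from diversity delta (missing %s or %s)", pid, from_tp, to_tp)
            continue
        rows.append(
            {
                "patient_id": pid,
                "shannon_from": retained[sid_from],
                "shannon_to": retained[sid_to],
                "delta": retained[sid_to] - retained[sid_from],
            }
        )
    return pd.DataFrame(rows, columns=["patient_id", "shannon_from", "shannon_to", "delta"])
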