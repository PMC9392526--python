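"""Published summary statistics of the 11-participant 3MDR veteran cohort.

The trial this package models released only score-level summaries: per-score
baseline mean and SD, the estimated linear slope (per unit of ordinal visit
coding), and the within-participant permutation p-value.  Individual-level
data were never deposited, so these numbers serve two roles here:

* defaults for the synthetic-cohort generator (:mod:`trajperm.simulate`),
  which emulates a cohort with this statistical structure, and
* the input to the Benjamini-Hochberg stage when reproducing the study's
  multiplicity correction from its reported p-values.

Scores are kept in the published row order.  ``CAPS5_*`` rows are the
clinician-administered PTSD interview (total symptom severity plus the
B/C/D/E symptom-cluster subtotals and the dissociation items); ``DERS18_*``
rows are the emotion-regulation questionnaire total and its six subscales.
"""

from __future__ import annotations

from types import MappingProxyType
from typing import NamedTuple


class ReportedScore(NamedTuple):
    """One published score row: baseline moments, fitted slope, p-value."""

    pre_mean: float
    pre_sd: float
    slope: float
    p_value: float


#: Published per-score results (baseline mean +/- SD, slope per visit step,
#: permutation p).  Slopes for instrument totals equal the sum of their
#: subscale slopes up to the printed rounding.
REPORTED_RESULTS: MappingProxyType[str, ReportedScore] = MappingProxyType(
    {
        "PCL5": ReportedScore(49.7, 12.6, -3.4, 0.00091),
        "MISSMSF": ReportedScore(61.2, 12.9, -2.3, 0.0039),
        "PHQ9": ReportedScore(14.7, 3.6, -1.2, 0.0012),
        "GAD7": ReportedScore(15.4, 3.7, -1.0, 0.015),
        "OQ45": ReportedScore(95.1, 15.5, -2.8, 0.0056),
        "PDEQ": ReportedScore(26.1, 9.9, -0.8, 0.055),
        "CDRISC25": ReportedScore(60.5, 14.2, 1.2, 0.030),
        "AUDIT": ReportedScore(5.1, 4.3, -0.0, 0.65),
        "CAPS5_TOTAL": ReportedScore(46.1, 9.1, -6.7, 0.0020),
        "CAPS5_B": ReportedScore(11.4, 2.3, -1.8, 0.0019),
        "CAPS5_C": ReportedScore(5.9, 1.8, -1.1, 0.0021),
        "CAPS5_D": ReportedScore(16.1, 4.1, -2.4, 0.0054),
        "CAPS5_E": ReportedScore(12.7, 3.9, -1.5, 0.031),
        "CAPS5_DISS": ReportedScore(1.2, 1.5, -0.1, 0.58),
        "DERS18": ReportedScore(56.5, 9.9, -3.8, 0.00003),
        "DERS18_AWARENESS": ReportedScore(9.4, 3.7, -0.1, 0.61),
        "DERS18_CLARITY": ReportedScore(9.2, 2.2, -0.5, 0.011),
        "DERS18_GOALS": ReportedScore(11.0, 2.2, -0.9, 0.027),
        "DERS18_IMPULSE": ReportedScore(8.4, 3.6, -1.0, 0.0042),
        "DERS18_NONACCEPTANCE": ReportedScore(10.4, 3.5, -0.6, 0.096),
        "DERS18_STRATEGIES": ReportedScore(8.1, 2.4, -0.7, 0.012),
    }
)

#: Number of participants in the published cohort.
N_PARTICIPANTS: int = 11

#: Published FDR threshold (largest rejected p) for the 21 scores above.
REPORTED_FDR_THRESHOLD: float = 0.031


def reported_pvalues() -> dict[str, float]:
    """Return the published permutation p-values keyed by score name."""
    return {name: row.p_value for name, row in REPORTED_RESULTS.items()}
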