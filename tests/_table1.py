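"""Reconstruction of the published benchmark cohort from its printed
marker x outcome counts.

For each age stratum and outcome the reference report prints, per cell of
n patients: how many were methylation-high, how many ER-negative, and how
many positive for the combined marker (methylation-high AND ER-negative).
Those marginals admit a consistent per-patient joint assignment in every
cell (combined <= min(meth, er) and meth + er - combined <= n), so a full
128-patient cohort carrying joint labels can be rebuilt and every printed
rate recomputed from scratch.
"""

from methmarker.core import CohortSet, ERStatus, SampleRecord

# stratum -> representative age; (outcome, n, meth_high, er_negative, combined)
TABLE1_CELLS = {
    (">55", 60): [(True, 28, 22, 23, 18), (False, 46, 8, 19, 5)],
    ("45-55", 50): [(True, 9, 5, 6, 3), (False, 18, 1, 7, 1)],
    ("<45", 40): [(True, 6, 3, 6, 3), (False, 21, 1, 4, 0)],
}


def build_cohort():
    """Per-sample cohort with joint (methylation, ER) labels matching every
    printed marginal.  Returns (samples, methylation_calls, er_calls)."""
    samples, meth_calls, er_calls = [], {}, {}
    idx = 0
    for (_, age), cells in TABLE1_CELLS.items():
        for pcr, n, meth, er_neg, both in cells:
            # `both` patients methylation-high & ER-negative, then the
            # remaining marker-positives disjointly, then double-negatives
            labels = (
                [(True, True)] * both
                + [(True, False)] * (meth - both)
                + [(False, True)] * (er_neg - both)
            )
            labels += [(False, False)] * (n - len(labels))
            for m, e in labels:
                idx += 1
                sid = f"T{idx:03d}"
                samples.append(
                    SampleRecord(
                        sample_id=sid,
                        cohort_set=CohortSet.screening,
                        pcr=pcr,
                        er_status=ERStatus.negative if e else ERStatus.positive,
                        age=age,
                    )
                )
                meth_calls[sid] = m
                er_calls[sid] = e
    return samples, meth_calls, er_calls
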