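"""Programmatic fixture: a cohort engineered to a published-style confusion pattern.

Builds input tables in which the algorithm arm has tp=26, tn=81, fp=15,
fn=6 (128 neonates) and the non-algorithm arm tp=34, tn=82, fp=10, fn=4
(130 neonates).  Gold status is induced by giving both expert annotators an
identical 60 s event; clinical positivity by a form mark at hour 0.
"""

from __future__ import annotations

import pandas as pd

PATTERNS = {
    "algorithm": {"tp": 26, "tn": 81, "fp": 15, "fn": 6},
    "non_algorithm": {"tp": 34, "tn": 82, "fp": 10, "fn": 4},
}


def engineered_cohort():
    ann_rows, clin_rows, meta_rows = [], [], []
    i = 0
    for group, counts in PATTERNS.items():
        for kind, n in counts.items():
            for _ in range(n):
                i += 1
                nid = f"N{i:04d}"
                gold = kind in ("tp", "fn")
                clin = kind in ("tp", "fp")
                if gold:
                    for aid in ("E1", "E2"):
                        ann_rows.append(
                            {"neonate_id": nid, "annotator_id": aid,
                             "start_s": 100.0, "end_s": 160.0}
                        )
                for k in range(2):
                    clin_rows.append(
                        {"neonate_id": nid, "hour_index": k,
                         "form_marked": int(clin and k == 0), "asm_given": 0,
                         "asm_therapeutic": 1}
                    )
                meta_rows.append(
                    {"neonate_id": nid, "hospital": f"H{(i % 8) + 1}", "group": group,
                     "recording_duration_h": 2.0, "start_datetime": ""}
                )
    return (
        pd.DataFrame(ann_rows, columns=["neonate_id", "annotator_id", "start_s", "end_s"]),
        pd.DataFrame(clin_rows),
        pd.DataFrame(meta_rows),
    )
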