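"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately re-derive results by exhaustive enumeration and must stay
independent of the package's incremental implementations.
"""

import datetime as dt

from panctriage.tools import RiskModel, qcancer_flag, qcancer_risk, rule_flag


def brute_force_evaluate(timeline, tool, config):
    """Enumerate every event-date cut and test the tool on the cut's event set.

    Returns (entry_date, flagged, flag_date, index_date) with the same
    stopping semantics as the spec: scanning covers [entry, entry+window],
    halts before any date strictly after the diagnosis, first flagging date
    wins, index = flag date if flagged else last tool-relevant event date
    seen before the halt.
    """
    tool_codes = tool.symptom_codes
    entry = None
    for ev in timeline.events:
        if ev.symptom_code in tool_codes:
            entry = ev.event_date
            break
    if entry is None:
        return None, False, None, None
    window_end = entry + dt.timedelta(days=config.accumulation_window_days)
    dx = timeline.cancer_diagnosis[0] if timeline.cancer_diagnosis else None

    dates = sorted({e.event_date for e in timeline.events if entry <= e.event_date <= window_end})
    flagged, flag_date, last_qual = False, None, None
    for d in dates:
        if dx is not None and d > dx:
            break
        codes = {
            e.symptom_code
            for e in timeline.events
            if entry <= e.event_date <= d  # full cut, recomputed from scratch
        }
        if any(e.symptom_code in tool_codes and e.event_date == d for e in timeline.events):
            last_qual = d
        age = timeline.age_at(d)
        if isinstance(tool, RiskModel):
            hit = qcancer_flag(
                qcancer_risk(
                    {
                        "age": age,
                        "sex": timeline.sex,
                        "symptoms": codes,
                        "bmi": timeline.bmi,
                        "deprivation": timeline.seifa_percentile,
                    },
                    tool,
                ),
                tool,
            )
        else:
            hit = rule_flag(codes, age, timeline.sex, tool)[0]
        if hit:
            flagged, flag_date = True, d
            break
    index = flag_date if flagged else last_qual
    return entry, flagged, flag_date, index


def random_timeline(rng, codes, p_cancer=0.5, max_events=8):
    """Small random timeline for oracle comparisons."""
    import datetime as dt

    from tests.conftest import make_timeline

    n = int(rng.integers(1, max_events + 1))
    base = dt.date(2012, 1, 1)
    events = [
        (base + dt.timedelta(days=int(rng.integers(0, 500))),
         codes[int(rng.integers(0, len(codes)))])
        for _ in range(n)
    ]
    dx = None
    if rng.random() < p_cancer:
        dx = base + dt.timedelta(days=int(rng.integers(0, 700)))
    sex = "male" if rng.random() < 0.5 else "female"
    birth = dt.date(int(1930 + rng.integers(0, 40)), 6, 15)
    return make_timeline(sex=sex, birth=birth, events=events, diagnosis=dx)
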