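"""Brute-force per-patient re-implementations used as independent oracles.

Everything here works on plain Python rows and explicit loops, deliberately
avoiding the package's pandas code paths so the tests compare two separate
derivations of each definition.
"""

from datetime import date, timedelta


def index_prior(labs, ref: date, lookback_days: int = 365, min_gap_days: int = 90):
    """labs: iterable of (date, egfr). Returns (index, index_date, prior, prior_date)."""
    start = ref - timedelta(days=lookback_days - 1)
    inside = [(d, g) for d, g in labs if start <= d <= ref]
    if not inside:
        return None
    idx_date = max(d for d, _ in inside)
    idx = min(g for d, g in inside if d == idx_date)
    cands = [(d, g) for d, g in inside if (idx_date - d).days >= min_gap_days]
    if not cands:
        return idx, idx_date, None, None
    pr_date = max(d for d, _ in cands)
    prior = min(g for d, g in cands if d == pr_date)
    return idx, idx_date, prior, pr_date


def tier(index, prior, has_code, aki, lo=30.0, hi=60.0):
    if prior is None:
        return "unclassified"
    if index < lo and prior < lo:
        return "high"
    if index < lo and lo <= prior < hi:
        return "excluded_aki" if aki else "intermediate"
    if lo <= index < hi and prior < lo and has_code:
        return "intermediate"
    if index >= lo and prior >= lo and has_code:
        return "low"
    return "unclassified"


def confusion_counts(pred, ref_pos, universe):
    tp = fp = fn = tn = 0
    for pid in universe:
        p, r = pid in pred, pid in ref_pos
        if p and r:
            tp += 1
        elif p:
            fp += 1
        elif r:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def followup_counts(members, labs_by_pid, index_date_by_pid, ref: date,
                    horizon_days: int = 180, threshold: float = 30.0):
    """Returns (n_subsequent, n_any_ge30, n_current_ge30) by explicit loops."""
    end = ref + timedelta(days=horizon_days)
    n_sub = n_any = n_cur = 0
    for pid in members:
        if pid not in index_date_by_pid:
            continue
        idx_date = index_date_by_pid[pid]
        fup = [(d, g) for d, g in labs_by_pid.get(pid, []) if idx_date < d <= end]
        if not fup:
            continue
        n_sub += 1
        if any(g >= threshold for _, g in fup):
            n_any += 1
        last_date = max(d for d, _ in fup)
        current = min(g for d, g in fup if d == last_date)
        if current >= threshold:
            n_cur += 1
    return n_sub, n_any, n_cur
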