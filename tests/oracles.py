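"""Independent brute-force rule evaluators used as oracles by the test suite.

These deliberately re-evaluate the published analysis rules with naive
per-element loops, sharing no code with the package implementation.
"""

import math


def brute_force_ipi_rules(press_times, entry_times, lick_times,
                          break_lick_count, break_gap, ultrafast_threshold):
    """Naive per-interval classification and sequence-boundary evaluation.

    Events at exactly a press time belong to the interval after that press.
    Returns (classes, boundaries) for the n-1 adjacent press pairs.
    """
    classes, boundaries = [], []
    for i in range(len(press_times) - 1):
        a, b = press_times[i], press_times[i + 1]
        ne = sum(1 for t in entry_times if a <= t < b)
        nl = sum(1 for t in lick_times if a <= t < b)
        ipi = b - a
        if ipi <= ultrafast_threshold and ne == 0 and nl == 0:
            klass = "ultrafast"
        elif nl >= break_lick_count:
            klass = "consumption"
        elif ipi >= break_gap:
            klass = "gap_break"
        elif ne >= 1:
            klass = "check"
        else:
            klass = "rapid"
        classes.append(klass)
        boundaries.append(nl >= break_lick_count or ipi >= break_gap)
    return classes, boundaries


def brute_force_steps(rungs, durations, direction_sign=1, min_duration=0.030):
    """Naive ladder step classification on an odd-high rung profile.

    ``rungs``/``durations`` describe the raw touch sequence; touches lasting
    <= min_duration are dropped first.  Returns a list of
    (step_length, klass, irregular_kind, excluded) tuples.
    """
    kept = [r for r, d in zip(rungs, durations) if d > min_duration]
    lengths = [direction_sign * (kept[i + 1] - kept[i]) for i in range(len(kept) - 1)]
    out = []
    for i, length in enumerate(lengths):
        low = kept[i] % 2 == 0 or kept[i + 1] % 2 == 0
        backward = False
        if length < 0:
            j = i
            while j - 1 >= 0 and lengths[j - 1] < 0:
                j -= 1
            k = i
            while k + 1 < len(lengths) and lengths[k + 1] < 0:
                k += 1
            backward = (k - j + 1) >= 2
        if length == 2 and not low:
            klass, kind = "small_regular", None
        elif length == 4 and not low:
            klass, kind = "large_regular", None
        else:
            klass = "irregular"
            if low:
                kind = "misstep"
            elif backward:
                kind = "backward"
            elif length > 4:
                kind = "leap"
            else:
                kind = "other"
        out.append((length, klass, kind, i == 0 or i == len(lengths) - 1))
    return out


def pearson_textbook(x, y):
    """Direct textbook Pearson correlation with scalar accumulation."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = math.sqrt(sum((a - mx) ** 2 for a in x))
    dy = math.sqrt(sum((b - my) ** 2 for b in y))
    return num / (dx * dy)
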