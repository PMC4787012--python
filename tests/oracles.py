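"""Independent brute-force oracles shared by the unit and acceptance suites."""

import numpy as np


def brute_force_status(levels, sides, alarm_windows, warning_windows,
                       same_side, upper_only=False):
    """Exhaustive enumeration of every sliding window of a k-of-m rule set.

    A k-of-m rule fires when k qualifying points fall within a span of at
    most m consecutive points (a run shorter than m is one truncated window).
    """

    def hit(min_level, windows):
        n = len(levels)
        for hits, length in windows:
            length = min(length, n)
            if length < hits:
                continue
            for start in range(n - length + 1):
                idx = range(start, start + length)
                if same_side and not upper_only:
                    for s in (1, -1):
                        if sum(1 for i in idx
                               if levels[i] >= min_level and sides[i] == s) >= hits:
                            return True
                else:
                    if sum(1 for i in idx if levels[i] >= min_level) >= hits:
                        return True
        return False

    if hit(3, alarm_windows):
        return "alarm"
    if hit(2, warning_windows):
        return "warning"
    return "normal"


def brute_force_cc(trace, ref_positions, segment, lag_window):
    """Exhaustive-lag Pearson cross-correlation oracle; ties resolved toward
    the smallest |lag| and then the negative lag."""
    results = []
    for lag in range(-lag_window, lag_window + 1):
        w = np.asarray(trace[segment.start + lag: segment.end + lag], float)
        r = np.corrcoef(w, ref_positions)[0, 1]
        results.append((r, -abs(lag), -max(lag, 0), lag))
    best = max(results)
    return best[0], best[3]
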