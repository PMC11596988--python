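"""Brute-force reference implementations, written directly from definitions.

These are deliberately independent of the package internals: plain Python
loops over label lists, no numpy vectorization, no shared helpers.  They
serve as oracles for the hypnogram metrics and transition counts.
"""

from __future__ import annotations

import math

STAGE_ORDER = ["W", "N1", "N2", "N3", "R"]
EPOCH_MIN = 0.5  # 30-s epochs


def brute_sleep_period(labels: list[str], min_epochs: int = 10) -> tuple[int, int]:
    """Scan every index for a run of >= min_epochs non-W epochs; end is one
    past the last non-W epoch.  Raises ValueError when no onset exists."""
    onset = None
    for i in range(len(labels)):
        run = labels[i:i + min_epochs]
        if len(run) == min_epochs and all(l != "W" for l in run):
            onset = i
            break
    if onset is None:
        raise ValueError("no persistent sleep onset")
    end = max(i for i, l in enumerate(labels) if l != "W") + 1
    return onset, end


def brute_quarters(onset: int, end: int) -> list[tuple[int, int]]:
    n = end - onset
    lengths = []
    for k in range(4):
        lengths.append(n // 4 + (1 if k < n % 4 else 0))
    ranges = []
    pos = onset
    for l in lengths:
        ranges.append((pos, pos + l))
        pos += l
    return ranges


def brute_ssi(labels: list[str], a: int, b: int) -> float:
    changes = 0
    for i in range(a, b - 1):
        if labels[i] != labels[i + 1]:
            changes += 1
    hours = (b - a) * EPOCH_MIN / 60.0
    return changes / hours


def brute_sleep_metrics(labels: list[str], onset: int, end: int) -> dict:
    window = labels[onset:end]
    n = len(window)
    out = {}
    for s in STAGE_ORDER:
        out[f"{s}-prop"] = sum(1 for l in window if l == s) / n
    out["TST"] = sum(1 for l in window if l != "W") * EPOCH_MIN
    out["SSI"] = brute_ssi(labels, onset, end)
    rem = [i for i, l in enumerate(window) if l == "R"]
    out["REMonSet"] = (rem[0] * EPOCH_MIN) if rem else n * EPOCH_MIN
    return out


def brute_quarter_metrics(labels: list[str], ranges: list[tuple[int, int]]) -> dict:
    out = {}
    for k, (a, b) in enumerate(ranges, start=1):
        window = labels[a:b]
        for s in STAGE_ORDER:
            out[f"{s}-Q{k}"] = sum(1 for l in window if l == s) / len(window)
        out[f"TST-Q{k}"] = sum(1 for l in window if l != "W") * EPOCH_MIN
        out[f"SSI-Q{k}"] = brute_ssi(labels, a, b)
    return out


def brute_transition_matrix(labels: list[str], a: int, b: int) -> list[list[float]]:
    counts = [[0] * 5 for _ in range(5)]
    for i in range(a, b - 1):
        counts[STAGE_ORDER.index(labels[i])][STAGE_ORDER.index(labels[i + 1])] += 1
    probs = []
    for row in counts:
        total = sum(row)
        probs.append([c / total if total else 0.0 for c in row])
    return probs


def brute_hypnodensity_features(rows: list[list[float]],
                                ranges: list[tuple[int, int]]) -> dict:
    out = {}
    pairs = [(i, j) for i in range(5) for j in range(i + 1, 5)]
    for k, (a, b) in enumerate(ranges, start=1):
        seg = rows[a:b]
        n = len(seg)
        for si, s in enumerate(STAGE_ORDER):
            out[f"p{s}-Q{k}"] = sum(r[si] for r in seg) / n
        for i, j in pairs:
            out[f"{STAGE_ORDER[i]}{STAGE_ORDER[j]}-Q{k}"] = (
                sum(r[i] * r[j] for r in seg) / n)
        ent = 0.0
        for r in seg:
            ent += -sum(p * math.log(p) for p in r if p > 0)
        out[f"entropy-Q{k}"] = ent / n
    return out
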