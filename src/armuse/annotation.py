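"""Multi-annotator code fusion and the binary functional / non-functional collapse.

The five per-frame behavioural codes are::

    -1  Unknown (arm out of camera view)            -> excluded
     0  no activity or movement                     -> nonfunctional
     1  nonfunctional movement (e.g. gait arm swing)-> nonfunctional
     2  nontask-related functional (gesturing)      -> functional
     3  task-related functional (opening a door)    -> functional

Per-sample codes from up to three annotators are fused by two-of-three
majority; samples with no majority, or whose majority is Unknown, become
Unknown and are excluded downstream.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .io import VALID_CODES

FUNCTIONAL = 1
NONFUNCTIONAL = 0
EXCLUDED = -1

#: Human-readable names for the three binary states, used in block tables.
LABEL_NAMES = {FUNCTIONAL: "functional", NONFUNCTIONAL: "nonfunctional",
               EXCLUDED: "excluded"}
LABEL_VALUES = {v: k for k, v in LABEL_NAMES.items()}


def _check_codes(codes) -> np.ndarray:
    try:
        codes = np.asarray(codes, dtype=int)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"codes must form a rectangular integer array: {exc}")
    if not np.isin(codes, VALID_CODES).all():
        bad = np.unique(codes[~np.isin(codes, VALID_CODES)])
        raise ValueError(f"invalid behavioural codes {bad.tolist()}")
    return codes


def merge_annotators(tracks: np.ndarray) -> np.ndarray:
    """Fuse 2 or 3 equal-length per-sample code sequences by majority vote.

    With three annotators a sample keeps a code iff at least two annotators
    agree on it; with two, both must agree.  No majority, or a majority of
    Unknown, yields -1.  The result is invariant under permutation of the
    annotators.
    """
    tracks = _check_codes(np.atleast_2d(tracks))
    if tracks.shape[0] not in (2, 3):
        raise ValueError("merge requires 2 or 3 annotator tracks")
    if tracks.ndim != 2:
        raise ValueError("tracks must share a common length")
    out = np.full(tracks.shape[1], EXCLUDED, dtype=int)
    if tracks.shape[0] == 2:
        agree = tracks[0] == tracks[1]
        out[agree] = tracks[0, agree]
    else:
        for i, j in ((0, 1), (0, 2), (1, 2)):
            agree = tracks[i] == tracks[j]
            out[agree] = tracks[i, agree]
    return out


def collapse_binary(codes: np.ndarray) -> np.ndarray:
    """Collapse behavioural codes to {functional, nonfunctional, excluded}.

    Codes 2 and 3 (both functional categories) map to :data:`FUNCTIONAL`;
    codes 0 and 1 to :data:`NONFUNCTIONAL`; Unknown stays :data:`EXCLUDED`.
    """
    codes = _check_codes(codes)
    out = np.full(codes.shape, EXCLUDED, dtype=int)
    out[(codes == 0) | (codes == 1)] = NONFUNCTIONAL
    out[(codes == 2) | (codes == 3)] = FUNCTIONAL
    return out


def block_label(binary: np.ndarray, start: int, end: int) -> tuple[int, float]:
    """Ground-truth label of the block ``[start, end)`` by simple majority.

    Excluded samples are removed from the denominator.  The block is
    functional if functional samples exceed half of the non-excluded samples,
    nonfunctional if nonfunctional samples reach at least half (an exact
    50/50 tie is resolved to the conservative non-use class).  A block in
    which fewer than half of the samples are non-excluded is itself excluded.

    Returns ``(label, purity)`` where purity is the majority-class share of
    the non-excluded samples (0.0 for an excluded block).
    """
    if not 0 <= start < end <= len(binary):
        raise ValueError(f"block [{start}, {end}) outside series bounds")
    window = np.asarray(binary[start:end])
    n = len(window)
    n_func = int(np.sum(window == FUNCTIONAL))
    n_nonf = int(np.sum(window == NONFUNCTIONAL))
    n_valid = n_func + n_nonf
    if n_valid < 0.5 * n or n_valid == 0:
        return EXCLUDED, 0.0
    purity = max(n_func, n_nonf) / n_valid
    if n_func > 0.5 * n_valid:
        return FUNCTIONAL, purity
    return NONFUNCTIONAL, purity


def export_labels_tsv(codes: np.ndarray, path: str | Path) -> None:
    """Write merged codes and their binary collapse as ``sample\tfaabos\tbinary``."""
    binary = collapse_binary(codes)
    frame = pd.DataFrame({
        "sample": np.arange(len(codes)),
        "faabos": codes,
        "binary": [LABEL_NAMES[b] for b in binary],
    })
    frame.to_csv(path, sep="\t", index=False)
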