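"""Independent brute-force particle measurement oracle.

Deliberately written without scikit-image or any shared code with the
package: labeling is a breadth-first flood fill, and the boundary chain
is traced counterclockwise (the package traces clockwise), so agreement
checks both code paths against the same geometric definition from
opposite orientations.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np

SQRT2 = math.sqrt(2.0)

# Moore neighborhood counterclockwise starting from West.
CCW = [(0, -1), (1, -1), (1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1)]
CCW_INDEX = {off: i for i, off in enumerate(CCW)}
STEP = [1.0 if dr == 0 or dc == 0 else SQRT2 for dr, dc in CCW]


def flood_fill_label(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """8-connected components via BFS flood fill."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    nr, nc = mask.shape
    for r0 in range(nr):
        for c0 in range(nc):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            comp = set()
            queue = deque([(r0, c0)])
            seen[r0, c0] = True
            while queue:
                r, c = queue.popleft()
                comp.add((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < nr and 0 <= cc < nc and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            queue.append((rr, cc))
            comps.append(comp)
    return comps


def ccw_chain_perimeter(comp: set[tuple[int, int]]) -> float:
    """Closed outer boundary chain length of one component, traced
    counterclockwise through pixel centers; single pixel -> 4."""
    if len(comp) == 1:
        return 4.0
    start = min(comp)  # row-major uppermost-leftmost; West neighbor is bg
    cur = start
    back = 0  # West
    per = 0.0
    seen: dict[tuple[tuple[int, int], int], float] = {}
    for _ in range(8 * len(comp) + 8):
        state = (cur, back)
        if state in seen:
            return per - seen[state]
        seen[state] = per
        nxt = None
        prev = back
        for k in range(1, 9):
            idx = (back + k) % 8
            pos = (cur[0] + CCW[idx][0], cur[1] + CCW[idx][1])
            if pos in comp:
                nxt = (idx, pos)
                break
            prev = idx
        if nxt is None:
            return 4.0
        idx, pos = nxt
        per += STEP[idx]
        back_pos = (cur[0] + CCW[prev][0], cur[1] + CCW[prev][1])
        cur = pos
        back = CCW_INDEX[(back_pos[0] - cur[0], back_pos[1] - cur[1])]
    raise RuntimeError("oracle tracing did not terminate")


def measure_mask(mask: np.ndarray) -> list[tuple[int, float]]:
    """(area, perimeter) of every component, sorted by area then perimeter."""
    out = [
        (len(comp), ccw_chain_perimeter(comp)) for comp in flood_fill_label(mask)
    ]
    return sorted(out)
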