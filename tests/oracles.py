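"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately re-derive results with the slowest, most literal
algorithms available (pure-python BFS, exhaustive minimisation) so they
share no code path with the package implementations they check.
"""

import math

import numpy as np


def oracle_link(mask: np.ndarray, min_overlap: int = 1) -> list[set]:
    """Exhaustive union-find over the section-linking rule.

    Per-section 8-connected components via BFS, then union of components
    in consecutive sections sharing >= ``min_overlap`` pixels.
    """
    n_sections = mask.shape[0]
    components: list[tuple[int, set]] = []
    for s in range(n_sections):
        seen = np.zeros(mask.shape[1:], dtype=bool)
        for r in range(mask.shape[1]):
            for c in range(mask.shape[2]):
                if mask[s, r, c] and not seen[r, c]:
                    comp = set()
                    queue = [(r, c)]
                    seen[r, c] = True
                    while queue:
                        rr, cc = queue.pop()
                        comp.add((rr, cc))
                        for dr in (-1, 0, 1):
                            for dc in (-1, 0, 1):
                                r2, c2 = rr + dr, cc + dc
                                if (
                                    0 <= r2 < mask.shape[1]
                                    and 0 <= c2 < mask.shape[2]
                                    and mask[s, r2, c2]
                                    and not seen[r2, c2]
                                ):
                                    seen[r2, c2] = True
                                    queue.append((r2, c2))
                    components.append((s, comp))

    parent = list(range(len(components)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, (si, ci) in enumerate(components):
        for j, (sj, cj) in enumerate(components):
            if sj == si + 1 and len(ci & cj) >= min_overlap:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    groups: dict[int, set] = {}
    for i, (s, comp) in enumerate(components):
        groups.setdefault(find(i), set()).update((s, r, c) for r, c in comp)
    return list(groups.values())


def oracle_min_edge_distance_um(
    centroid_nm: tuple[float, float, float],
    edge_mask: np.ndarray,
    pixel_size_nm: float,
    thickness_nm: float,
) -> float:
    """Literal minimum over every edge voxel of the 3D Euclidean distance."""
    x, y, z = centroid_nm
    best = math.inf
    for es, er, ec in zip(*np.nonzero(edge_mask)):
        d = math.sqrt(
            (es * thickness_nm - z) ** 2
            + (er * pixel_size_nm - y) ** 2
            + (ec * pixel_size_nm - x) ** 2
        )
        best = min(best, d)
    return best / 1000.0
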