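"""Regenerate the four-class Ramachandran region grids shipped as package data.

Run from anywhere: writes into src/nbens/data/ next to this script's repo.

Core and allowed regions are rectilinear approximations of the classic
PROCHECK-style map; the generous region is a 20-degree periodic dilation
of the allowed region.  Grids are 36x36 (10-degree cells), rows = phi from
-180, columns = psi from -180, labels F (most favored), A (additionally
allowed), G (generously allowed), D (disallowed).
"""

from pathlib import Path

import numpy as np
from scipy.ndimage import binary_dilation

DATA = Path(__file__).resolve().parent.parent / "src" / "nbens" / "data"

N = 36  # 10-degree cells


def rect_mask(rects):
    mask = np.zeros((N, N), dtype=bool)
    for pmin, pmax, qmin, qmax in rects:
        i0, i1 = (int(pmin) + 180) // 10, (int(pmax) + 180) // 10
        j0, j1 = (int(qmin) + 180) // 10, (int(qmax) + 180) // 10
        mask[i0:i1, j0:j1] = True
    return mask


def mirror(rects):
    return [(-pmax, -pmin, -qmax, -qmin) for pmin, pmax, qmin, qmax in rects]


def dilate(mask, cells):
    # periodic dilation: tile 3x3, dilate, take the center tile
    structure = np.ones((2 * cells + 1, 2 * cells + 1), dtype=bool)
    tiled = np.tile(mask, (3, 3))
    out = binary_dilation(tiled, structure=structure)
    return out[N:2 * N, N:2 * N]


def build(core_rects, allowed_rects, generous_cells=2):
    core = rect_mask(core_rects)
    allowed = rect_mask(allowed_rects) | core
    generous = dilate(allowed, generous_cells)
    grid = np.full((N, N), "D", dtype="U1")
    grid[generous] = "G"
    grid[allowed] = "A"
    grid[core] = "F"
    return grid


def write(path, grid, title):
    with open(path, "w") as fh:
        fh.write(f"# {title}\n")
        fh.write("# rows: phi from -180 to 170 step 10; "
                 "columns: psi from -180 to 170 step 10\n")
        fh.write("# F=most favored, A=additionally allowed, "
                 "G=generously allowed, D=disallowed\n")
        for row in grid:
            fh.write(" ".join(row) + "\n")


GENERAL_CORE = [
    (-170, -50, 100, 180),   # beta
    (-170, -50, -180, -170),  # beta, psi wrap
    (-150, -40, -70, 0),     # right-handed alpha
    (50, 70, 30, 60),        # left-handed alpha
]
GENERAL_ALLOWED = [
    (-180, -20, 60, 180),
    (-180, -20, -180, -160),
    (-180, -20, -110, 30),
    (-180, -140, 160, 180),
    (20, 100, -20, 90),
]

GLY_CORE = GENERAL_CORE + mirror(GENERAL_CORE)
GLY_ALLOWED = GENERAL_ALLOWED + mirror(GENERAL_ALLOWED)

PRO_CORE = [
    (-90, -40, -60, 0),
    (-90, -40, 110, 180),
]
PRO_ALLOWED = [
    (-110, -30, -80, 30),
    (-110, -30, 60, 180),
    (-110, -30, -180, -160),
]

write(DATA / "rama_general.txt",
      build(GENERAL_CORE, GENERAL_ALLOWED, 2),
      "Ramachandran four-class region grid (general residues)")
write(DATA / "rama_gly.txt",
      build(GLY_CORE, GLY_ALLOWED, 3),
      "Ramachandran four-class region grid (glycine)")
write(DATA / "rama_pro.txt",
      build(PRO_CORE, PRO_ALLOWED, 2),
      "Ramachandran four-class region grid (proline)")
print("done")
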