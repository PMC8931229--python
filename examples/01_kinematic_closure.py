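"""Analytic kinematic closure of a protein loop.

Builds a synthetic helix-loop-helix mini-protein, poses the closure
problem for its 6-residue loop (fixed anchors, fixed nonpivot torsions),
and enumerates every combination of the three pivot residues' phi/psi
torsions that exactly reconnects the chain.
"""

import numpy as np

from loopforge import (ClosureProblem, FixtureSpec, PivotSelection,
                       make_fixture, solve_closure, torsions_from_coords)
from loopforge.structure import SegmentSpec

structure, segment = make_fixture(FixtureSpec(loop_length=6, seed=3))
print(f"fixture: {len(structure)} residues, loop {segment.chain_id}:"
      f"{segment.start}-{segment.end}")

pivots = PivotSelection((segment.start, segment.start + 2, segment.end))
problem = ClosureProblem.from_structure(structure, segment, pivots)
solutions = solve_closure(problem)

native = torsions_from_coords(structure, segment)
nat_pivots = native[[0, 2, segment.length - 1], :2]
print(f"{len(solutions)} closure solutions (pivots at residues "
      f"{pivots.pivot_resnums}):")
for k, t in enumerate(solutions.pivot_torsions):
    dev = np.max(np.abs(((t - nat_pivots) + 180) % 360 - 180))
    tag = "  <- native conformation" if dev < 1e-3 else ""
    print(f"  solution {k}: residual {solutions.closure_residuals[k]:.1e} A, "
          f"pivot phi/psi {np.round(t.ravel(), 1)}{tag}")
print("Every solution reconnects the backbone exactly; one of them is the"
      " loop's own native conformation, recovered to numerical precision.")
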