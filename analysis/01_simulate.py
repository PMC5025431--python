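"""Simulate the two-group switching-covariance study and write it to disk.

Generates a three-state scenario in which the case-like group dwells twice
as long in a designated state whose connectivity carries a larger fraction
of weak edges, then writes per-subject time courses, motion stubs, ground
truth and the input manifest under scratch/sim/ (large, regenerable data
stays out of results/).

Run from the repository root:  python analysis/01_simulate.py [--seed 1]
"""

import argparse

import dfcstates as d

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--subjects", type=int, nargs=2, default=(20, 14),
                    help="control/case group sizes (demonstration scale; "
                    "the emulated study had 44 and 31)")
parser.add_argument("--out", default="scratch/sim")
args = parser.parse_args()

scenario = d.make_paper_like_scenario(
    k_states=3,
    weak_fraction_shift=0.5,
    dwell_ratio=2.0,
    seed=args.seed,
    n_subjects=tuple(args.subjects),
)
manifest = d.simulate_to_dir(scenario, args.out, overwrite=True)

n = manifest.groupby("group").size()
print(f"wrote {len(manifest)} subjects to {args.out} "
      f"({n.to_dict()}), 170 timepoints x 54 regions each")
print("designated state 1: case dwell x2, ~50% of its elevated blocks weak")
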