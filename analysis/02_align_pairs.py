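#!/usr/bin/env python
"""Pairwise whole-genome alignment of the simulated trio.

Aligns the pivot against each wild genome and the two wild genomes against
each other (unique-k-mer anchors, chain + extend, one-to-one filtering) and
tabulates block counts, aligned fractions and mean identity per pair.
"""

import argparse
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

import pandas as pd

from tripan import io
from tripan.pipeline import align_trio, trio_scenario

OUTDIR = os.path.join(os.path.dirname(__file__), "..", "results", "analysis")


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=7)
    args = parser.parse_args()
    os.makedirs(OUTDIR, exist_ok=True)

    trio = trio_scenario(args.seed)
    alignments = align_trio(trio)
    rows = []
    for (ref_name, qry_name), blocks in alignments.items():
        coords_rows = []
        for b in blocks:
            coords_rows.extend(b.split_at_large_gaps(10))
        io.write_coords(coords_rows, os.path.join(
            OUTDIR, f"{ref_name}_{qry_name}.coords"))
        ref_len = trio["genomes"][ref_name].total_length
        covered = sum(iv.length for b in blocks
                      for iv in b.ref_aligned_intervals(10))
        ident = (sum(b.identity * b.ref.length for b in blocks)
                 / sum(b.ref.length for b in blocks))
        rows.append({"pair": f"{ref_name}-{qry_name}", "blocks": len(blocks),
                     "ref_aligned_frac": round(covered / ref_len, 4),
                     "mean_identity": round(ident, 4)})
    table = pd.DataFrame(rows)
    table.to_csv(os.path.join(OUTDIR, "02_alignment_summary.tsv"), sep="\t",
                 index=False)
    print(table.to_string(index=False))
    print("\nUnaligned residue and sub-unity identity reflect the planted "
          "segmental variation: large gap columns count against block "
          "identity, and specific sequence stays uncovered.")


if __name__ == "__main__":
    main()
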