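"""Compute relative cut frequencies for each simulated digest.

Reads the peptide tables and manifests written by 01_simulate_digests.py,
runs the score filter / significance gate / ratio pipeline, and writes per
digest: the P1 x time frequency matrix, per-time cleavage-site counts
(per-time-point and cumulative), and a QC report.
"""

import argparse
from pathlib import Path

import pandas as pd

from taucleave import (
    TimeSeriesDesign,
    compute_cut_frequency,
    load_substrate,
    read_peptide_table,
    site_counts,
    tau_2n4r,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    tau = tau_2n4r()
    for name in ("soluble", "fibrillar", "cn"):
        table_path = args.outdir / f"digest_{name}.tsv"
        if not table_path.exists():
            print(f"{name}: no table at {table_path}, run 01 first")
            continue
        design = TimeSeriesDesign.from_manifest(args.outdir / f"manifest_{name}.tsv")
        substrate = (
            tau if name != "cn" else load_substrate(args.outdir / "tau_cn.fasta")
        )
        peptides = read_peptide_table(table_path, design=design)
        result = compute_cut_frequency(peptides, substrate, design)
        result.matrix.to_tsv(args.outdir / f"frequencies_{name}.tsv", substrate)
        counts = pd.DataFrame(
            {
                "time_s": result.matrix.time_points,
                "sites": site_counts(result.matrix).to_numpy(),
                "sites_cumulative": site_counts(
                    result.matrix, cumulative=True
                ).to_numpy(),
            }
        )
        counts.to_csv(args.outdir / f"site_counts_{name}.tsv", sep="\t", index=False)
        result.qc.to_json(args.outdir / f"qc_{name}.json")
        print(
            f"{name}: {result.qc.n_contributing} contributing peptides, "
            f"{len(result.matrix.sites)} sites, final-time site count "
            f"{int(counts['sites'].iloc[-1])}"
        )


if __name__ == "__main__":
    main()
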