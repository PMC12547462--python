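"""Fragment maps, P1-site classes and specificity profiles.

For the soluble and fibrillar digests: groups accepted peptides into
gapless fragments per time point (BED-like TSV + JSON), classifies every
detected P1 site by its maximum relative cut frequency, and tabulates the
amino-acid distribution five residues each way around the detected sites.
"""

import argparse
from pathlib import Path

from taucleave import (
    TimeSeriesDesign,
    aa_distribution,
    build_fragment_map,
    classify_sites,
    compute_cut_frequency,
    read_peptide_table,
    tau_2n4r,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    tau = tau_2n4r()
    for name in ("soluble", "fibrillar"):
        table_path = args.outdir / f"digest_{name}.tsv"
        if not table_path.exists():
            print(f"{name}: no table at {table_path}, run 01 first")
            continue
        design = TimeSeriesDesign.from_manifest(args.outdir / f"manifest_{name}.tsv")
        peptides = read_peptide_table(table_path, design=design)
        result = compute_cut_frequency(peptides, tau, design)

        fmap = build_fragment_map({design.time_points[-1]: result.matches}, tau)
        fmap.to_bed(args.outdir / f"fragments_{name}.bed.tsv")
        fmap.to_json(args.outdir / f"fragments_{name}.json")

        classes = classify_sites(result.matrix, tau)
        classes.to_csv(args.outdir / f"site_classes_{name}.tsv", sep="\t", index=False)
        tally = classes["site_class"].value_counts().sort_index()

        profile = aa_distribution(result.matrix.sites, tau)
        profile.to_csv(args.outdir / f"specificity_{name}.tsv", sep="\t")

        peps, cls = fmap.totals(design.time_points[-1])
        print(
            f"{name}: final-time fragments={len(fmap.entries[design.time_points[-1]])} "
            f"(Peps={peps}, Cls={cls}); class tally "
            + ", ".join(f"{c}:{n}" for c, n in tally.items())
        )


if __name__ == "__main__":
    main()
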