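"""Rebuild the packaged default fitness landscape from vendored inputs.

Offline utility: reads the vendored gene lists and per-chromosome annotation
summary under ``src/cinsim/data`` and writes ``default_landscape.tsv`` there.
The output is a synthetic reconstruction (documented curation, not a measured
dataset); rerunning this script is only needed when the vendored inputs
change.

Usage: python scripts/build_landscape.py
"""

from __future__ import annotations

import pathlib

import pandas as pd

from cinsim.features import CHROMS, density_from_gene_list, normalize_density

DATA = pathlib.Path(__file__).resolve().parents[1] / "src" / "cinsim" / "data"


def main() -> None:
    summary = pd.read_csv(DATA / "chromosome_summary.tsv", sep="\t", comment="#")
    summary["chrom"] = summary["chrom"].astype(str)
    summary = summary.set_index("chrom").loc[list(CHROMS)]
    lengths = summary["length_mb"].to_dict()

    bcell = pd.read_csv(DATA / "bcell_genes.tsv", sep="\t", comment="#")
    leuk = pd.read_csv(DATA / "leukemia_mutation_genes.tsv", sep="\t", comment="#")
    driver = pd.read_csv(DATA / "driver_genes.tsv", sep="\t", comment="#")

    alpha, alpha_genes = density_from_gene_list(bcell, lengths)
    # leukemia-mutation genes already counted in the B-cell track are dropped
    beta, beta_genes = density_from_gene_list(leuk, lengths, exclude=alpha_genes)
    gamma, _ = density_from_gene_list(driver, lengths)

    s_gd = normalize_density(summary["coding_genes"], summary["length_mb"])
    s_cen = normalize_density(summary["centromere_mb"], [1.0] * len(CHROMS))

    out = pd.DataFrame(
        {
            "chrom": list(CHROMS),
            "alpha": alpha.round(6),
            "beta": beta.round(6),
            "gamma": gamma.round(6),
            "s_gd": s_gd.round(6),
            "s_cen": s_cen.round(6),
        }
    )
    header = (
        "# Default per-chromosome fitness landscape (synthetic reconstruction).\n"
        "# Built by scripts/build_landscape.py from the vendored gene lists and\n"
        "# chromosome_summary.tsv; all five tracks are max-normalized densities.\n"
        "# Version: 1\n"
    )
    path = DATA / "default_landscape.tsv"
    with open(path, "w") as fh:
        fh.write(header)
        out.to_csv(fh, sep="\t", index=False)
    print(f"wrote {path} ({len(beta_genes)} beta genes after overlap removal)")


if __name__ == "__main__":
    main()
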