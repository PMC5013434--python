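#!/usr/bin/env python
"""Test the somatic-maintenance vs reproduction trade-off signature:
metabolic gene-set representation among +CE transcripts, testis-biased
representation among -CE transcripts (Yates 2x2 chi-square with adjusted
standardized residuals), and the tau tissue-specificity comparison
between the two CE directions (Wilcoxon-Mann-Whitney).
"""

from pathlib import Path

import pandas as pd

from clinexp import enrich, io

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ce = io.read_table(ROOT / "ce_results.tsv")
    gene_sets = io.read_gene_sets(ROOT / "synthetic" / "gene_sets.gmt")
    profiles = io.read_tissue_profiles(ROOT / "synthetic" / "tissue_profiles.tsv")

    rows = []
    for gs in gene_sets:
        for direction in ("+CE", "-CE"):
            try:
                res = enrich.set_representation(ce, direction, gs)
            except ValueError as exc:
                print(f"{gs.name}/{direction}: skipped ({exc})")
                continue
            rows.append({
                "set": gs.name, "direction": direction, "chi2": res.chi2,
                "p": res.p, "residual_focal": res.residuals[0, 0],
                "representation": res.direction,
            })
            print(f"{gs.name:14s} among {direction}: chi2 = {res.chi2:7.2f}, "
                  f"p = {res.p:.3g}, adj. residual = {res.residuals[0, 0]:+.2f} "
                  f"({res.direction}-represented)")
    io.write_table(pd.DataFrame(rows), ROOT / "enrichment.tsv")

    taus = enrich.tau_table(profiles)
    flags = profiles.apply(lambda r: enrich.classify_testis_biased(r, 50.0), axis=1)
    io.write_table(
        pd.DataFrame({"transcript_id": profiles.index, "tau": taus.values,
                      "testis_biased": flags.values}),
        ROOT / "tau.tsv",
    )
    pos = taus.loc[taus.index.intersection(
        ce.loc[ce["direction"] == "+CE", "transcript_id"])].dropna()
    neg = taus.loc[taus.index.intersection(
        ce.loc[ce["direction"] == "-CE", "transcript_id"])].dropna()
    if len(pos) and len(neg):
        w, p = enrich.compare_tau(pos.to_numpy(), neg.to_numpy())
        print(f"tau comparison, +CE (n={len(pos)}, median {pos.median():.3f}) vs "
              f"-CE (n={len(neg)}, median {neg.median():.3f}): W = {w:.0f}, p = {p:.3g}")


if __name__ == "__main__":
    main()
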