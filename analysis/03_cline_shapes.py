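#!/usr/bin/env python
"""Fit the four cline-shape models (null, linear, sigmoid/tanh, step) to
every clinally expressed transcript and select the best by AIC.

A linear cline indicates expression tracking a changing local optimum; a
sigmoid or step indicates a switch between alternative expression states
maintained against dispersal.
"""

from pathlib import Path

import pandas as pd

from clinexp import io, shapes

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    values = pd.read_csv(ROOT / "normalized_cpm.tsv", sep="\t", index_col=0)
    meta = io.read_metadata(ROOT / "synthetic" / "metadata.tsv")
    lat = meta.set_index("sample_id").loc[values.columns, "latitude"].to_numpy()
    ce = io.read_table(ROOT / "ce_results.tsv")

    ce_ids = ce.loc[ce["direction"].isin(["+CE", "-CE"]), "transcript_id"].tolist()
    res = shapes.fit_all(values, lat, transcript_ids=ce_ids)
    io.write_table(res, ROOT / "shape_results.tsv")

    freq = res["selected_model"].value_counts()
    print(f"fitted {len(res)} CE transcripts")
    print("selected cline shapes:")
    for model, n in freq.items():
        print(f"  {model:8s} {n:5d} ({100 * n / len(res):.1f}%)")
    steplike = res[res["selected_model"].isin(["step", "sigmoid"])]
    if len(steplike):
        centres = steplike.apply(
            lambda r: r.get("c") if r["selected_model"] == "sigmoid" else r.get("l_c"),
            axis=1,
        ).dropna()
        print(f"median transition position: {centres.median():.1f} degrees north of "
              "the southernmost site")


if __name__ == "__main__":
    main()
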