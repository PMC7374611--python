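"""Extract semantic components from the frame labels and interpret them.

Filters labels at the 90% confidence cut, averages embeddings per frame,
fits the 50-component PCA and reports explained variance, the top/bottom
frame label histograms for the first components, and the post-hoc binary
label regression.  Writes components and interpretation tables under
results/semantics/.
"""
from pathlib import Path

import numpy as np
import pandas as pd

from semenc import io, pipeline, semantic

OUT = Path(__file__).resolve().parent.parent / "results" / "semantics"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    study = pipeline.simulate_experiment(seed=SEED)
    comps = study.components
    io.write_components(comps, OUT / "components")
    evr = comps.explained_variance_ratio
    print(f"50 components keep {100 * evr.sum():.2f}% of embedding variance; "
          f"top five: {np.round(100 * evr[:5], 1)}%")

    rows = []
    for k in range(5):
        bottom, top, hists = semantic.rank_frames(comps, k, 0.10, table=study.table)
        top_labels = sorted(hists[1], key=hists[1].get, reverse=True)[:5]
        bot_labels = sorted(hists[0], key=hists[0].get, reverse=True)[:5]
        rows.append(dict(component=k, evr_pct=round(100 * evr[k], 2),
                         top_labels=",".join(top_labels),
                         bottom_labels=",".join(bot_labels)))
        print(f"  component {k}: top {top_labels} vs bottom {bot_labels}")
    pd.DataFrame(rows).to_csv(OUT / "component_interpretation.tsv", sep="\t", index=False)

    labels = semantic.binary_label_matrix(study.table)
    weights, r2, f = semantic.posthoc_label_regression(comps, labels, k_top=5)
    print(f"post-hoc label regression: R^2 = {r2:.4f}, F = {f:.0f} "
          f"({weights.shape[0]} labels)")
    pd.DataFrame(weights, index=labels.label_ids).to_csv(
        OUT / "label_weights.tsv", sep="\t", header=[f"c{k}" for k in range(5)]
    )


if __name__ == "__main__":
    main()
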