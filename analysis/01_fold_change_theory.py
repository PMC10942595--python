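"""Fold-change theory of repressing a degradable template.

Maps the steady-state fold change over the (k_on*R, k_off) plane with and
without template degradation, classifies the operating regime of the
measured regulator presets, and inverts the observed 2.5-fold ceiling into
an elongation leakage fraction.

Writes results/fold_change_map.csv and results/regime_classification.csv.
"""

from pathlib import Path

import pandas as pd

from transrep import presets
from transrep.foldchange import (
    FoldChangeContext,
    classify_regime,
    default_grid,
    fold_change,
    fold_change_map,
    leakage_from_max_fold,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)


def main() -> None:
    eps = leakage_from_max_fold(presets.ORIGINAL_MAX_FOLD)
    print(f"2.5-fold ceiling at saturating repressor implies "
          f"elongation leakage = {eps:.0%}")

    grid = default_grid(n=40)
    frames = []
    for delta, label in ((0.0, "stable_template"),
                         (presets.MRNA_DEGRADATION_PER_MIN, "mrna")):
        fmap = fold_change_map(grid, grid, leakage=0.1, degradation=delta)
        frames.append(fmap.to_frame().assign(template=label))
    pd.concat(frames, ignore_index=True).to_csv(
        RESULTS / "fold_change_map.csv", index=False, float_format="%.5g")
    print("fold-change heatmap grids -> results/fold_change_map.csv "
          "(iso-fold contours are straight lines only for the stable template)")

    ctx = FoldChangeContext(regulator_conc=1000.0, leakage=eps,
                            degradation=presets.MRNA_DEGRADATION_PER_MIN)
    rows = []
    for name in ("original", "mutant1", "mutant5", "ms2cp"):
        kin = presets.KINETICS_PRESETS[name]
        rows.append({
            "preset": name,
            "k_on_per_nM_min": kin.k_on,
            "k_off_per_min": kin.k_off,
            "kd_nM": kin.k_d,
            "residence_min": kin.residence_time,
            "regime_at_1uM": classify_regime(kin, ctx),
            "fold_at_1uM": fold_change(kin, ctx),
        })
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "regime_classification.csv", index=False)
    print(table.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
    print("the slow-unbinding phage protein operates out of equilibrium at "
          "mRNA half-lives of ~5 min; the fast-cycling repressor does not")


if __name__ == "__main__":
    main()
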