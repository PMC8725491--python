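"""Quality control and allele frequencies on the breed panel.

Injects 2% random missingness, 30 markers with heavy (10%) dropout and 3
samples with heavy dropout, applies the MAF > 0.01 / call-rate > 0.95
filters, mean-imputes the survivors and writes the per-marker B-allele
frequencies.  Outputs: results/qc_report.tsv, results/allele_frequencies.tsv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _panels import RESULTS, SEED, breeds_panel

import herdstat as h


def main() -> None:
    data = h.inject_missingness(breeds_panel(), marker_rate=0.02, seed=SEED)
    rng = np.random.default_rng(SEED)
    X = data.dosages
    bad_markers = rng.choice(data.n_markers, 30, replace=False)
    for j in bad_markers:  # 10% dropout: call rate 0.90 < 0.95
        X[rng.choice(data.n_samples, data.n_samples // 10, replace=False), j] = np.nan
    bad_samples = rng.choice(data.n_samples, 3, replace=False)
    for i in bad_samples:
        X[i, rng.choice(data.n_markers, data.n_markers // 10, replace=False)] = np.nan
    clean, report = h.apply_qc(data, h.QCThresholds())
    print(
        f"QC: removed {report.markers_removed_by_rule['call_rate']} markers on "
        f"call rate, {report.markers_removed_by_rule['maf']} on MAF, "
        f"{report.samples_removed} samples; retained "
        f"{report.markers_retained} markers x {report.samples_retained} samples"
    )
    imputed = h.mean_impute(clean)
    freqs = h.allele_frequencies(imputed)
    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(
        [
            {
                "markers_removed_call_rate": report.markers_removed_by_rule["call_rate"],
                "markers_removed_maf": report.markers_removed_by_rule["maf"],
                "samples_removed": report.samples_removed,
                "markers_retained": report.markers_retained,
                "samples_retained": report.samples_retained,
            }
        ]
    ).to_csv(RESULTS / "qc_report.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "marker": imputed.markers["id"],
            "b_allele_freq": freqs.frequencies,
            "n_samples": freqs.n_samples_used,
        }
    ).to_csv(RESULTS / "allele_frequencies.tsv", sep="\t", index=False)
    print(f"mean B-allele frequency {freqs.frequencies.mean():.3f}; tables written")


if __name__ == "__main__":
    main()
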