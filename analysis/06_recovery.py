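"""Method-recovery experiment: who is fooled by the composition shift?

Replicated simulations under the `robust_like` preset are analysed by a
stationary amino-acid model (JTT+G+F), RY-recoded nucleotide ML and
LogDet-distance NJ.  Because the shift moves probability within the
purine and pyrimidine classes, RY coding is nearly blind to it, and
LogDet is consistent under the generating process; the stationary
amino-acid analysis sees the full convergent signal.  The null control
(no shift) checks that all methods recover the generating topology when
the model assumptions hold.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from mitobias.simulate import recovery_experiment, robust_like_config

RESULTS = Path(__file__).resolve().parents[1] / "results"
METHODS = ("aa_jtt_ml", "ry_ml", "logdet_nj")
N_REPS = 20  # narrative run; the acceptance script uses 50


def main() -> None:
    cfg = robust_like_config(n_per_group=4, n_codons=4000, seed=7)
    df = recovery_experiment(cfg, methods=METHODS, n_reps=N_REPS, seed=7)
    df.to_csv(RESULTS / "recovery_shifted.tsv", sep="\t")
    print("Shifted preset (proportion of replicates):")
    print(df.round(2).to_string())

    null = robust_like_config(n_per_group=4, n_codons=4000, seed=7, shifted=False)
    df0 = recovery_experiment(null, methods=METHODS, n_reps=N_REPS, seed=11)
    df0.to_csv(RESULTS / "recovery_null.tsv", sep="\t")
    print("\nNull control:")
    print(df0.round(2).to_string())

    mis = df["naked_coral"]
    print(
        f"\naa JTT ML mis-grouped the shifted clade in {mis['aa_jtt_ml']:.0%} of "
        f"replicates, vs {mis['ry_ml']:.0%} (RY ML) and "
        f"{mis['logdet_nj']:.0%} (LogDet NJ)."
    )


if __name__ == "__main__":
    main()
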