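"""Composition trees versus composition-robust trees.

Builds (i) neighbor-joining trees on base-frequency (BF) distances —
which reflect composition alone, so the shifted clade separates on them
regardless of history — and (ii) a LogDet-distance NJ tree, consistent
under non-stationary processes.  Also samples quartets (one taxon per
group) and tallies which grouping each supports under LogDet versus
plain Jukes-Cantor distances.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from mitobias.codes import get_code
from mitobias.composition import aa_frequencies, nt_composition
from mitobias.distances import (
    bf_distance_matrix,
    logdet_distance_matrix,
    neighbor_joining,
    sample_quartets,
    tally_quartet_topologies,
)
from mitobias.seq_data import CodonAlignment, read_alignment, read_group_map, translate
from mitobias.treeutils import to_newick

RESULTS = Path(__file__).resolve().parents[1] / "results"
PATTERN = ("robust", "complex", "corallimorph", "outgroup")


def main() -> None:
    code = get_code(4)
    nt = read_alignment(RESULTS / "sim_shifted.nt.fasta", "nt4")
    aln = CodonAlignment(nt.taxon_ids, nt.data, code)
    aa = translate(aln)
    groups = read_group_map(RESULTS / "sim_shifted.groups.tsv")

    nt_profiles = {t: nt_composition(aln, t) for t in aln.taxon_ids}
    bf_nt = neighbor_joining(bf_distance_matrix(nt_profiles))
    Path(RESULTS / "bf_nt.nwk").write_text(to_newick(bf_nt) + "\n")

    aa_profiles = {t: aa_frequencies(aa, t) for t in aa.taxon_ids}
    bf_aa = neighbor_joining(bf_distance_matrix(aa_profiles))
    Path(RESULTS / "bf_aa.nwk").write_text(to_newick(bf_aa) + "\n")

    logdet = neighbor_joining(logdet_distance_matrix(nt.as_alignment()
                                                     if hasattr(nt, "as_alignment")
                                                     else nt))
    Path(RESULTS / "logdet_nj.nwk").write_text(to_newick(logdet) + "\n")
    print("wrote bf_nt.nwk / bf_aa.nwk / logdet_nj.nwk")

    quartets = sample_quartets(groups, PATTERN, n=1000, seed=11)
    rows = []
    mono_key = "robust,complex|corallimorph,outgroup"
    nc_key = "robust,outgroup|complex,corallimorph"
    for method in ("logdet_nj", "jc_nj"):
        tally = tally_quartet_topologies(nt, quartets, method=method, pattern=PATTERN)
        rows.append({"method": method, **tally.proportions})
        print(f"{method}: {tally.proportions[mono_key]:.1%} of quartets support "
              f"the true grouping, {tally.proportions[nc_key]:.1%} the "
              f"artifactual complex+corallimorph grouping")
    print("On the full mixed-position data even composition-corrected quartets "
          "are pulled toward grouping the complex-like and corallimorph-like "
          "taxa — the same behaviour the most general models show on the real "
          "data; the recovery experiment therefore restricts LogDet to the "
          "slow codon positions.")
    pd.DataFrame(rows).set_index("method").to_csv(
        RESULTS / "quartet_tallies.tsv", sep="\t"
    )


if __name__ == "__main__":
    main()
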