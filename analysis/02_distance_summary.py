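#!/usr/bin/env python
"""Infra/interspecific distance structure of the default assemblage.

Computes the K2P pairwise matrix, the infra/interspecific summary (min,
max, mean, median, counts past the 3% threshold) and the binned distance
histogram that visualises the barcode gap.  On the default regime the
infraspecific mean sits near 1.5% with maxima around 7% in deep-split
species, against interspecific distances centred near 17%.
"""

from pathlib import Path

from motudelim import distance_summary, pairwise_distances, read_alignment, read_specimen_table
from motudelim.distances import summary_table, write_phylip

SEED = 42
ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "scratch" / "assemblages" / "default"
RESULTS = ROOT / "results"


def main() -> None:
    if not DATA.exists():
        raise SystemExit("run analysis/01_simulate_assemblage.py first")
    aln = read_alignment(DATA / "alignment.fasta")
    labels = read_specimen_table(DATA / "truth.tsv")
    dm = pairwise_distances(aln, "k80")
    s = distance_summary(dm, labels, t=0.03)

    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "distance_summary.tsv").write_text(summary_table(s))
    lines = ["bin_low\tbin_high\tinfraspecific\tinterspecific"]
    infra = s.histogram.get("infraspecific")
    inter = s.histogram.get("interspecific")
    for b in range(max(len(infra), len(inter))):
        lines.append(
            f"{b * s.bin_width:.2f}\t{(b + 1) * s.bin_width:.2f}\t"
            f"{int(infra[b]) if b < len(infra) else 0}\t"
            f"{int(inter[b]) if b < len(inter) else 0}"
        )
    (RESULTS / "distance_histogram.tsv").write_text("\n".join(lines) + "\n")
    write_phylip(dm, ROOT / "scratch" / "k2p_matrix.phy")

    print(
        f"infraspecific: mean {s.infraspecific.mean:.4f}, "
        f"median {s.infraspecific.median:.4f}, max {s.infraspecific.max:.4f}"
    )
    print(
        f"interspecific: mean {s.interspecific.mean:.4f}, min {s.interspecific.min:.4f}"
    )
    print(
        f"species with max infraspecific K2P > 3%: {s.n_species_infra_gt_t}; "
        f"species pairs with min interspecific < 3%: {s.n_pairs_inter_lt_t}"
    )


if __name__ == "__main__":
    main()
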