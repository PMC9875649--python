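"""Assign pharmacogene families and derive the ROS gene set.

Families come from symbol-prefix rules (CYP/ABC/SLC/...); the ROS set is
keyword matching (oxidative, stress, oxygen, reactive) against GO term
names in the fixture's annotation table, with CYP and ABC families removed
after matching.  Writes results/categories.tsv.
"""

import argparse
from pathlib import Path

from spatialpgx.categorize import assign_families, read_go_annotations, ros_genes
from spatialpgx.io import read_gene_list, write_table
from spatialpgx.pipeline import load_fixture_dir

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--fixture", type=Path, default=ROOT / "results" / "fixture")
    ap.add_argument("--blocklist", type=Path, default=None,
                    help="optional file of curated-out GO term names/ids")
    args = ap.parse_args()

    panel = read_gene_list(args.fixture / "panel.tsv")
    # restrict to symbols actually present in the matrices
    matrices, _, _ = load_fixture_dir(args.fixture)
    present = set(next(iter(matrices.values())).genes)
    from spatialpgx.io import GeneList

    panel = GeneList(symbols=[g for g in panel.symbols if g in present],
                     families=panel.families)

    blocklist = []
    if args.blocklist and args.blocklist.is_file():
        blocklist = [l.strip() for l in args.blocklist.read_text().splitlines() if l.strip()]

    families = assign_families(panel)
    assignment = ros_genes(
        read_go_annotations(args.fixture / "go_annotations.tsv"),
        panel,
        blocklist=blocklist,
        family_assignment=families,
    )
    write_table(assignment.to_frame(), ROOT / "results" / "categories.tsv")

    fam_counts = {}
    for fam in families.families.values():
        fam_counts[fam] = fam_counts.get(fam, 0) + 1
    print("panel family sizes:", dict(sorted(fam_counts.items())))
    ros = assignment.ros_genes()
    print(f"{len(ros)} ROS genes from {len(assignment.matched_term_set())} matched GO terms")
    print("ROS genes:", ", ".join(ros))


if __name__ == "__main__":
    main()
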