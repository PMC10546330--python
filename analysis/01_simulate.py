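"""Generate the default synthetic study dataset and write it to results/data.

Produces a 2,000-gene interaction network with a degree-balanced 100-gene
planted trait module, two species' GWAS gene tables (40 seeds each, half
from the module), a noisy ortholog map and a 40-term phenotype ontology
whose first branch is enriched for module genes.
"""

import sys
from pathlib import Path

from crossloc import SyntheticConfig, generate_all
from crossloc import io

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    config = SyntheticConfig(rng_seed=SEED)
    network, truth, ontology, annotations = generate_all(config)
    out = io.ensure_dir(OUT)
    io.write_edge_list(network, out / "network.tsv")
    io.write_gmt(
        {"seeds_a": truth.seeds_a, "seeds_b": truth.seeds_b, "module": truth.module_genes},
        out / "gene_sets.gmt",
    )
    io.write_gene_table(truth.gene_table_a, out / "genes_a.tsv")
    io.write_gene_table(truth.gene_table_b, out / "genes_b.tsv")
    io.write_ortholog_table(truth.ortholog_map, out / "orthologs.tsv")
    io.write_ontology(ontology, out / "ontology.tsv")
    io.write_annotations(annotations.direct, out / "annotations.tsv")
    (out / "trait_terms.txt").write_text("\n".join(sorted(truth.trait_terms)) + "\n")
    print(
        f"dataset (seed {SEED}): {network.number_of_nodes()} genes, "
        f"{network.number_of_edges()} edges, module {len(truth.module_genes)}, "
        f"seeds {len(truth.seeds_a)}/{len(truth.seeds_b)} -> {out}"
    )


if __name__ == "__main__":
    main()
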