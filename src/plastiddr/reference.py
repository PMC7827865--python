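"""Reference compendium for 19 deposited lycophyte plastomes.

Shipped as package data: per-species summary statistics (lengths of the
quadripartite regions, gene counts by category with repeat-duplicate
parentheticals, repeat orientation, GC content, accession) and the intron
presence/absence survey over the 19 canonical intron-containing plastid
genes. These are the published values for the deposited records named in
the ``accession`` column; they serve as inputs for group-level arithmetic
and as the intron-catalog schema.
"""

from __future__ import annotations

import importlib.resources as resources

import pandas as pd

# species abbreviations used in the intron table -> full names
SPECIES_ABBREVIATIONS = {
    "H.lu": "Huperzia lucidula",
    "H.se": "Huperzia serrata",
    "I.fl": "Isoetes flaccida",
    "S.ly": "Selaginella lyallii",
    "S.kra": "Selaginella kraussiana",
    "S.rem": "Selaginella remotifolia",
    "S.ind": "Selaginella indica",
    "S.va": "Selaginella vardei",
    "S.lep": "Selaginella lepidophylla",
    "S.san": "Selaginella sanguinolenta",
    "S.st": "Selaginella stauntoniana",
    "S.ta": "Selaginella tamariscina",
    "S.doe": "Selaginella doederleinii",
    "S.inv": "Selaginella involvens",
    "S.mo": "Selaginella moellendorffii",
    "S.bis": "Selaginella bisulcata",
    "S.pen": "Selaginella pennata",
    "S.hai": "Selaginella hainanensis",
    "S.un": "Selaginella uncinata",
}

_STATE = {"+": "present", "-": "absent", ".": "gene-missing"}


def _data_path(name: str):
    return resources.files("plastiddr.data").joinpath(name)


def load_plastome_table() -> pd.DataFrame:
    """Summary statistics for the 19 deposited lycophyte plastomes."""
    with resources.as_file(_data_path("lycophyte_plastomes.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    df["genus"] = df["species"].str.split().str[0]
    df["is_selaginella"] = df["genus"] == "Selaginella"
    return df


def load_intron_table() -> pd.DataFrame:
    """Long-format intron survey: species, gene, category, intron_index, state.

    ``state`` is present/absent/gene-missing (gene-missing covers both lost
    and pseudogenized genes, which the survey cannot score).
    """
    with resources.as_file(_data_path("lycophyte_introns.tsv")) as p:
        wide = pd.read_csv(p, sep="\t")
    rows = []
    for _, r in wide.iterrows():
        for abbr, species in SPECIES_ABBREVIATIONS.items():
            rows.append(
                {
                    "species": species,
                    "gene": r["gene"],
                    "category": r["category"],
                    "intron_index": int(r["intron_index"]),
                    "state": _STATE[str(r[abbr])],
                }
            )
    return pd.DataFrame(rows)


def intron_catalog() -> dict[str, dict]:
    """The canonical intron-containing plastid genes.

    Maps gene name -> {"category": protein|tRNA, "max_introns": 1 or 2}.
    """
    with resources.as_file(_data_path("lycophyte_introns.tsv")) as p:
        wide = pd.read_csv(p, sep="\t")
    catalog: dict[str, dict] = {}
    for _, r in wide.iterrows():
        entry = catalog.setdefault(
            r["gene"], {"category": r["category"], "max_introns": 0}
        )
        entry["max_introns"] = max(entry["max_introns"], int(r["intron_index"]))
    return catalog


def load_gene_synonyms() -> dict[str, str]:
    with resources.as_file(_data_path("gene_synonyms.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return dict(zip(df["alias"], df["canonical"]))
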