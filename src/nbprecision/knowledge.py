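"""Gene/drug knowledge base used for CNV selection and actionability grading.

A small curated table ships with the package: gene records (symbol, functional
role, cancer-predisposition flag, pathway label) and drug records (target
gene, drug name, action mechanism, evidence level, development stage).  The
table covers the recurrently targetable neuroblastoma genes (ALK, MYCN, ATRX,
CDK6, CCND1, MDM2, PIK3CA, CDKN2A/B, ...) with at least one drug record each,
so cohort fixtures can be built without querying external databases.

Evidence levels make priority grading deterministic: ``validated_direct``
marks an alteration-drug match validated for direct targeting (approved or
investigational agent); ``pathway_predicted`` marks a novel alteration in a
targetable gene or pathway.  Immune-checkpoint agents for hypermutated or
MSI-high tumors are keyed to the pseudo-target symbol ``IMMUNE_CHECKPOINT``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = ["KnowledgeBase", "GENE_ROLES", "DRUG_MECHANISMS", "EVIDENCE_LEVELS", "DRUG_STAGES"]

GENE_ROLES = frozenset({"oncogene", "tumor_suppressor", "both", "unknown"})
DRUG_MECHANISMS = frozenset({"inhibitor", "antagonist", "agonist", "other"})
EVIDENCE_LEVELS = frozenset({"validated_direct", "pathway_predicted"})
DRUG_STAGES = frozenset({"approved", "investigational"})

CHECKPOINT_TARGET = "IMMUNE_CHECKPOINT"

_GENE_COLS = ["symbol", "role", "predisposition_flag", "pathway"]
_DRUG_COLS = ["gene", "drug", "mechanism", "evidence", "stage"]


@dataclass
class KnowledgeBase:
    """Gene and drug record tables with closed vocabularies."""

    genes: pd.DataFrame
    drugs: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = set(_GENE_COLS) - set(self.genes.columns)
        if missing:
            raise ValueError(f"knowledge base gene table missing columns: {sorted(missing)}")
        missing = set(_DRUG_COLS) - set(self.drugs.columns)
        if missing:
            raise ValueError(f"knowledge base drug table missing columns: {sorted(missing)}")
        bad_roles = set(self.genes["role"]) - GENE_ROLES
        if bad_roles:
            raise ValueError(f"unknown gene roles: {sorted(bad_roles)}")
        bad = set(self.drugs["mechanism"]) - DRUG_MECHANISMS
        if bad:
            raise ValueError(f"unknown drug mechanisms: {sorted(bad)}")
        bad = set(self.drugs["evidence"]) - EVIDENCE_LEVELS
        if bad:
            raise ValueError(f"unknown evidence levels: {sorted(bad)}")
        bad = set(self.drugs["stage"]) - DRUG_STAGES
        if bad:
            raise ValueError(f"unknown drug stages: {sorted(bad)}")
        orphan = set(self.drugs["gene"]) - set(self.genes["symbol"])
        if orphan:
            raise ValueError(f"drug records reference unknown genes: {sorted(orphan)}")

    # -- lookups -----------------------------------------------------------

    def has_gene(self, symbol: str) -> bool:
        return symbol in set(self.genes["symbol"])

    def role(self, symbol: str) -> str:
        rows = self.genes.loc[self.genes["symbol"] == symbol, "role"]
        return rows.iloc[0] if len(rows) else "unknown"

    def pathway(self, symbol: str) -> str:
        rows = self.genes.loc[self.genes["symbol"] == symbol, "pathway"]
        return rows.iloc[0] if len(rows) else ""

    def is_tumor_suppressor(self, symbol: str) -> bool:
        return self.role(symbol) in {"tumor_suppressor", "both"}

    def is_oncogene(self, symbol: str) -> bool:
        return self.role(symbol) in {"oncogene", "both"}

    def drugs_for(self, symbol: str) -> pd.DataFrame:
        return self.drugs[self.drugs["gene"] == symbol].reset_index(drop=True)

    def checkpoint_drugs(self) -> pd.DataFrame:
        return self.drugs_for(CHECKPOINT_TARGET)

    def predisposition_genes(self) -> frozenset[str]:
        flags = self.genes["predisposition_flag"].astype(bool)
        return frozenset(self.genes.loc[flags, "symbol"])

    # -- io ----------------------------------------------------------------

    @classmethod
    def load(cls, gene_path: str | Path, drug_path: str | Path) -> "KnowledgeBase":
        genes = pd.read_csv(gene_path, sep="\t")
        drugs = pd.read_csv(drug_path, sep="\t")
        genes["predisposition_flag"] = genes["predisposition_flag"].astype(bool)
        return cls(genes=genes, drugs=drugs)

    @classmethod
    def load_default(cls) -> "KnowledgeBase":
        """Load the knowledge base packaged with the library."""
        data = resources.files("nbprecision") / "data"
        return cls.load(str(data / "kb_genes.tsv"), str(data / "kb_drugs.tsv"))

    def write(self, gene_path: str | Path, drug_path: str | Path) -> None:
        self.genes.to_csv(gene_path, sep="\t", index=False)
        self.drugs.to_csv(drug_path, sep="\t", index=False)
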