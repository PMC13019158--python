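"""Genotype container shared by the simulator and the population-statistics code.

A :class:`GenotypeMatrix` holds unphased alternate-allele dosages (0/1/2,
``-1`` for missing) for bi-allelic autosomal SNVs, one population label per
sample, and per-site annotations (gene, consequence class).  It round-trips
through a minimal unphased VCF dialect and through plain dosage TSV tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "gene", "consequence"]

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


@dataclass
class GenotypeMatrix:
    """Samples x sites alternate-allele dosage matrix with metadata.

    Parameters
    ----------
    sample_ids
        Sample identifiers, one per row of ``dosages``.
    population_labels
        Population label per sample (same length as ``sample_ids``).
    sites
        DataFrame with columns ``chrom, pos, ref, alt, gene, consequence``;
        the index provides site identifiers. Positions are 1-based.
    dosages
        Integer array of shape (n_samples, n_sites) with values in
        {0, 1, 2, -1}; -1 marks a missing call.
    """

    sample_ids: list
    population_labels: np.ndarray
    sites: pd.DataFrame
    dosages: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.population_labels = np.asarray(self.population_labels)
        self.dosages = np.asarray(self.dosages)
        n_samples, n_sites = self.dosages.shape
        if len(self.sample_ids) != n_samples:
            raise ValueError("sample_ids length does not match dosage rows")
        if len(self.population_labels) != n_samples:
            raise ValueError("need exactly one population label per sample")
        if len(self.sites) != n_sites:
            raise ValueError("site table length does not match dosage columns")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2} or -1 (missing)")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    @property
    def site_ids(self) -> pd.Index:
        return self.sites.index

    @property
    def populations(self) -> list:
        """Unique population labels in order of first appearance."""
        return list(pd.unique(self.population_labels))

    def subset_sites(self, site_ids) -> "GenotypeMatrix":
        idx = self.sites.index.get_indexer(site_ids)
        if (idx < 0).any():
            raise KeyError("unknown site id in subset request")
        return GenotypeMatrix(
            sample_ids=self.sample_ids,
            population_labels=self.population_labels,
            sites=self.sites.iloc[idx].copy(),
            dosages=self.dosages[:, idx].copy(),
        )

    # ------------------------------------------------------------------ I/O

    def to_vcf(self, path) -> None:
        """Write the minimal unphased VCF dialect (GT only, 1-based pos)."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene">\n')
            fh.write(
                '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">\n'
            )
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(str(s) for s in self.sample_ids)
                + "\n"
            )
            for j, (site_id, row) in enumerate(self.sites.iterrows()):
                info = f"GENE={row['gene']};CSQ={row['consequence']}"
                gts = "\t".join(_GT_STRINGS[int(d)] for d in self.dosages[:, j])
                fh.write(
                    f"{row['chrom']}\t{int(row['pos'])}\t{site_id}\t"
                    f"{row['ref']}\t{row['alt']}\t.\tPASS\t{info}\tGT\t{gts}\n"
                )

    @classmethod
    def from_vcf(cls, path, population_labels=None) -> "GenotypeMatrix":
        """Read a bi-allelic SNV VCF via cyvcf2 into a dosage matrix.

        Multi-allelic records raise; missing calls map to -1.
        """
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        records, dosage_cols = [], []
        for var in vcf:
            if len(var.ALT) != 1:
                raise ValueError(f"site {var.ID or var.POS} is not bi-allelic")
            gts = np.asarray(var.gt_types)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            dos = np.select(
                [gts == 0, gts == 1, gts == 3], [0, 1, 2], default=MISSING
            )
            records.append(
                {
                    "id": var.ID or f"{var.CHROM}:{var.POS}",
                    "chrom": var.CHROM,
                    "pos": var.POS,
                    "ref": var.REF,
                    "alt": var.ALT[0],
                    "gene": var.INFO.get("GENE", "."),
                    "consequence": var.INFO.get("CSQ", "."),
                }
            )
            dosage_cols.append(dos)
        sites = pd.DataFrame(records).set_index("id")[SITE_COLUMNS]
        dosages = np.column_stack(dosage_cols) if dosage_cols else np.empty((len(samples), 0), int)
        if population_labels is None:
            population_labels = np.array(["pop0"] * len(samples))
        else:
            population_labels = np.asarray(
                [population_labels[s] for s in samples]
                if isinstance(population_labels, dict)
                else population_labels
            )
        return cls(samples, population_labels, sites, dosages)

    def to_dosage_tsv(self, path) -> None:
        """Sites as rows (with annotation columns), samples as columns."""
        dose = pd.DataFrame(self.dosages.T, index=self.sites.index,
                            columns=[str(s) for s in self.sample_ids])
        df = pd.concat([self.sites, dose], axis=1)
        df.to_csv(path, sep="\t", index_label="site_id")

    @classmethod
    def from_dosage_tsv(cls, path, population_labels=None) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="site_id")
        sites = df[SITE_COLUMNS].copy()
        sample_cols = [c for c in df.columns if c not in SITE_COLUMNS]
        dosages = df[sample_cols].to_numpy(dtype=int).T
        if population_labels is None:
            population_labels = np.array(["pop0"] * len(sample_cols))
        elif isinstance(population_labels, dict):
            population_labels = np.asarray([population_labels[s] for s in sample_cols])
        return cls(sample_cols, np.asarray(population_labels), sites, dosages)


def read_population_labels(path) -> dict:
    """Two-column sample->population TSV (no header required)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"],
                     dtype=str, comment="#")
    return dict(zip(df["sample"], df["population"]))


def write_population_labels(g: GenotypeMatrix, path) -> None:
    pd.DataFrame(
        {"sample": [str(s) for s in g.sample_ids], "population": g.population_labels}
    ).to_csv(path, sep="\t", header=False, index=False)
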