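"""Genetic-load scoring: allele polarization, coding-effect classes,
Grantham deleteriousness, and the derived-homozygote load ratio.

The load of an individual is summarized per mutation class (loss of
function, missense, Grantham-deleterious missense, synonymous) as

    load_ratio = 2 H / (2 H + X)

with H the number of derived-homozygous sites (two derived alleles per
site) and X the number of derived-heterozygous sites (one per site).  A
ratio near 1 means most derived deleterious alleles are exposed in
homozygotes (realized load); a low ratio means they ride along masked in
heterozygotes.

Ancestral states are inferred from two conjoined criteria: the allele
homozygous in more than half of the ingroup individuals, provided the
outgroup is homozygous for the same allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genes import Gene, GeneSet, revcomp, translate
from .io import MISSING, GenotypeTable, LineageMap

# Grantham (1974) amino-acid distances: derived from the composition /
# polarity / volume formula with the mean over the 190 unordered pairs
# normalized to 100 and rounded to integers.
_GRANTHAM: dict[tuple[str, str], int] = {
    ("A","C"):195, ("A","D"):126, ("A","E"):107, ("A","F"):113, ("A","G"):60, ("A","H"):86,
    ("A","I"):94, ("A","K"):106, ("A","L"):96, ("A","M"):85, ("A","N"):111, ("A","P"):27,
    ("A","Q"):91, ("A","R"):111, ("A","S"):99, ("A","T"):58, ("A","V"):65, ("A","W"):148,
    ("A","Y"):112, ("C","D"):154, ("C","E"):170, ("C","F"):205, ("C","G"):158, ("C","H"):174,
    ("C","I"):198, ("C","K"):202, ("C","L"):198, ("C","M"):196, ("C","N"):139, ("C","P"):169,
    ("C","Q"):154, ("C","R"):180, ("C","S"):112, ("C","T"):149, ("C","V"):191, ("C","W"):215,
    ("C","Y"):194, ("D","E"):45, ("D","F"):177, ("D","G"):94, ("D","H"):81, ("D","I"):168,
    ("D","K"):102, ("D","L"):172, ("D","M"):160, ("D","N"):23, ("D","P"):108, ("D","Q"):61,
    ("D","R"):96, ("D","S"):66, ("D","T"):85, ("D","V"):152, ("D","W"):191, ("D","Y"):160,
    ("E","F"):140, ("E","G"):98, ("E","H"):41, ("E","I"):134, ("E","K"):57, ("E","L"):139,
    ("E","M"):126, ("E","N"):41, ("E","P"):94, ("E","Q"):29, ("E","R"):54, ("E","S"):80,
    ("E","T"):66, ("E","V"):121, ("E","W"):152, ("E","Y"):123, ("F","G"):153, ("F","H"):100,
    ("F","I"):21, ("F","K"):102, ("F","L"):22, ("F","M"):29, ("F","N"):158, ("F","P"):114,
    ("F","Q"):116, ("F","R"):97, ("F","S"):155, ("F","T"):103, ("F","V"):50, ("F","W"):40,
    ("F","Y"):22, ("G","H"):98, ("G","I"):136, ("G","K"):127, ("G","L"):138, ("G","M"):127,
    ("G","N"):79, ("G","P"):42, ("G","Q"):87, ("G","R"):125, ("G","S"):55, ("G","T"):59,
    ("G","V"):109, ("G","W"):184, ("G","Y"):147, ("H","I"):94, ("H","K"):32, ("H","L"):99,
    ("H","M"):86, ("H","N"):68, ("H","P"):76, ("H","Q"):24, ("H","R"):29, ("H","S"):89,
    ("H","T"):47, ("H","V"):84, ("H","W"):115, ("H","Y"):83, ("I","K"):102, ("I","L"):5,
    ("I","M"):10, ("I","N"):149, ("I","P"):96, ("I","Q"):109, ("I","R"):98, ("I","S"):142,
    ("I","T"):89, ("I","V"):30, ("I","W"):61, ("I","Y"):33, ("K","L"):106, ("K","M"):95,
    ("K","N"):94, ("K","P"):103, ("K","Q"):53, ("K","R"):26, ("K","S"):121, ("K","T"):78,
    ("K","V"):97, ("K","W"):110, ("K","Y"):85, ("L","M"):14, ("L","N"):153, ("L","P"):98,
    ("L","Q"):113, ("L","R"):102, ("L","S"):144, ("L","T"):92, ("L","V"):32, ("L","W"):61,
    ("L","Y"):36, ("M","N"):141, ("M","P"):87, ("M","Q"):101, ("M","R"):92, ("M","S"):135,
    ("M","T"):81, ("M","V"):22, ("M","W"):67, ("M","Y"):35, ("N","P"):90, ("N","Q"):46,
    ("N","R"):85, ("N","S"):46, ("N","T"):65, ("N","V"):133, ("N","W"):174, ("N","Y"):142,
    ("P","Q"):75, ("P","R"):103, ("P","S"):73, ("P","T"):38, ("P","V"):68, ("P","W"):147,
    ("P","Y"):110, ("Q","R"):43, ("Q","S"):68, ("Q","T"):41, ("Q","V"):96, ("Q","W"):130,
    ("Q","Y"):99, ("R","S"):109, ("R","T"):71, ("R","V"):96, ("R","W"):101, ("R","Y"):77,
    ("S","T"):58, ("S","V"):123, ("S","W"):177, ("S","Y"):143, ("T","V"):70, ("T","W"):128,
    ("T","Y"):92, ("V","W"):88, ("V","Y"):55, ("W","Y"):37,
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GRANTHAM_DELETERIOUS_THRESHOLD = 150

#: recognized mutation classes for load accounting
CLASSES = ("LOF", "missense", "deleterious_gs", "synonymous")


def grantham_score(aa_from: str, aa_to: str) -> int:
    """Grantham physicochemical distance between two standard amino acids.

    Symmetric; 0 for identical residues.  Stop codons and nonstandard
    symbols are outside the domain.
    """
    for aa in (aa_from, aa_to):
        if aa not in AMINO_ACIDS:
            raise ValueError(f"not a standard amino acid: {aa!r}")
    if aa_from == aa_to:
        return 0
    key = (aa_from, aa_to) if aa_from < aa_to else (aa_to, aa_from)
    return _GRANTHAM[key]


def is_grantham_deleterious(score: int) -> bool:
    """Missense changes with Grantham score >= 150 are treated as deleterious."""
    return score >= GRANTHAM_DELETERIOUS_THRESHOLD


# ---------------------------------------------------------------------------
# Ancestral polarization
# ---------------------------------------------------------------------------


@dataclass
class AncestralCall:
    """Polarization of one site: which of ref/alt is ancestral, and how."""

    site_index: int
    ancestral: str | None       # "ref", "alt", or None when unresolved
    method: str                 # "both", "majority-homozygote", "outgroup", "unresolved"

    @property
    def resolved(self) -> bool:
        return self.ancestral is not None

    def derived_dosage(self, genotype: int) -> int | None:
        """Count of derived alleles for a dosage genotype (None if missing)."""
        if genotype == MISSING or not self.resolved:
            return None
        return genotype if self.ancestral == "ref" else 2 - genotype


def polarize_ancestral(
    table: GenotypeTable,
    outgroup: str,
    require_both: bool = True,
) -> list[AncestralCall]:
    """Infer the ancestral allele at every site.

    An allele is ancestral when it is homozygous in strictly more than 50%
    of the ingroup individuals (the outgroup excluded from the count) *and*
    the outgroup is homozygous for the same allele.  When the two criteria
    disagree the site is unresolved.  When the outgroup call is missing the
    majority criterion alone decides, flagged ``majority-homozygote``.  With
    ``require_both=False``, a homozygous outgroup also resolves sites that
    lack an ingroup majority (flagged ``outgroup``).
    """
    og_idx = table.sample_index(outgroup)
    in_idx = [j for j in range(table.n_samples) if j != og_idx]
    gt = table.genotypes
    calls: list[AncestralCall] = []
    for i in range(table.n_sites):
        g = gt[i, in_idx]
        n = int((g != MISSING).sum())
        majority: str | None = None
        if n > 0:
            if (g == 0).sum() > n / 2:
                majority = "ref"
            elif (g == 2).sum() > n / 2:
                majority = "alt"
        og = int(gt[i, og_idx])
        og_allele = {0: "ref", 2: "alt"}.get(og)

        if og_allele is None:
            if majority is not None:
                calls.append(AncestralCall(i, majority, "majority-homozygote"))
            else:
                calls.append(AncestralCall(i, None, "unresolved"))
        elif majority is None:
            if require_both:
                calls.append(AncestralCall(i, None, "unresolved"))
            else:
                calls.append(AncestralCall(i, og_allele, "outgroup"))
        elif majority == og_allele:
            calls.append(AncestralCall(i, majority, "both"))
        else:
            calls.append(AncestralCall(i, None, "unresolved"))  # conflict
    return calls


# ---------------------------------------------------------------------------
# Coding-effect classification
# ---------------------------------------------------------------------------


class ReferenceMismatchError(ValueError):
    """A site's REF base disagrees with the annotated coding sequence."""


@dataclass
class EffectClass:
    site_index: int
    effect: str                     # LOF | missense | synonymous | noncoding/other
    gene_id: str | None = None
    aa_change: str | None = None    # e.g. "D12E" (ancestral -> derived)
    grantham: int | None = None

    @property
    def deleterious_gs(self) -> bool:
        return self.grantham is not None and is_grantham_deleterious(self.grantham)


def _coding_strand_allele(base: str, strand: str) -> str:
    return base if strand == "+" else revcomp(base)


def _classify_site(
    gene: Gene, pos1: int, ref: str, alt: str, ancestral: str | None
) -> EffectClass | None:
    """Classify one site against one gene; None when outside the gene."""
    if gene.splice_region(pos1) and gene.cds_offset(pos1) is None:
        return EffectClass(-1, "LOF", gene.gene_id)
    off = gene.cds_offset(pos1)
    if off is None:
        return None
    ref_c = _coding_strand_allele(ref, gene.strand)
    alt_c = _coding_strand_allele(alt, gene.strand)
    if gene.cds[off] != ref_c:
        raise ReferenceMismatchError(
            f"{gene.gene_id} {gene.chrom}:{pos1}: REF {ref} is {ref_c} on the "
            f"coding strand but the CDS has {gene.cds[off]}"
        )
    codon, within = gene.codon_at(off)
    # orient substitution ancestral -> derived; default ref -> alt
    anc_c, der_c = (alt_c, ref_c) if ancestral == "alt" else (ref_c, alt_c)
    anc_codon = codon[:within] + anc_c + codon[within + 1:]
    der_codon = codon[:within] + der_c + codon[within + 1:]
    aa_anc = translate(anc_codon)
    aa_der = translate(der_codon)
    codon_no = off // 3 + 1
    if aa_anc == aa_der:
        return EffectClass(-1, "synonymous", gene.gene_id)
    if aa_der == "*":
        return EffectClass(-1, "LOF", gene.gene_id,
                           aa_change=f"{aa_anc}{codon_no}*")
    if aa_anc == "*":
        # stop-lost: an amino-acid altering change outside the LOF definition
        return EffectClass(-1, "noncoding/other", gene.gene_id,
                           aa_change=f"*{codon_no}{aa_der}")
    gs = grantham_score(aa_anc, aa_der)
    return EffectClass(-1, "missense", gene.gene_id,
                       aa_change=f"{aa_anc}{codon_no}{aa_der}", grantham=gs)


def classify_effects(
    table: GenotypeTable,
    genes: GeneSet,
    ancestral: Sequence[AncestralCall] | None = None,
) -> list[EffectClass]:
    """Classify the coding consequence of every site's derived allele.

    The derived allele (from ``ancestral``; ref->alt when a site is
    unpolarized) is substituted into the annotated codon and translated:
    stop gains and splice-dinucleotide SNVs are LOF, amino-acid changes are
    missense (with Grantham score), silent changes are synonymous, and
    anything outside annotated genes is ``noncoding/other``.
    """
    anc_lookup: dict[int, str | None] = {}
    if ancestral is not None:
        anc_lookup = {c.site_index: c.ancestral for c in ancestral}
    out: list[EffectClass] = []
    for i, row in enumerate(table.sites.itertuples(index=False)):
        hit = None
        for gene in genes.genes_at(row.chrom, row.pos):
            hit = _classify_site(gene, row.pos, row.ref, row.alt, anc_lookup.get(i))
            if hit is not None:
                break
        if hit is None:
            hit = EffectClass(-1, "noncoding/other")
        hit.site_index = i
        out.append(hit)
    return out


def effects_to_frame(table: GenotypeTable, effects: Sequence[EffectClass]) -> pd.DataFrame:
    rows = []
    for e in effects:
        site = table.sites.iloc[e.site_index]
        rows.append(
            (site["chrom"], site["pos"], e.effect, e.gene_id, e.aa_change,
             e.grantham, e.deleterious_gs)
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "effect", "gene", "aa_change", "grantham",
                 "deleterious_gs"],
    )


# ---------------------------------------------------------------------------
# Load ratio
# ---------------------------------------------------------------------------


@dataclass
class LoadProfile:
    sample: str
    counts: dict[str, tuple[int, int]]        # class -> (n_derived_hom, n_derived_het)

    def ratio(self, cls: str) -> float | None:
        h, x = self.counts.get(cls, (0, 0))
        if h == 0 and x == 0:
            return None
        return 2 * h / (2 * h + x)


def _class_of(effect: EffectClass, cls: str) -> bool:
    if cls == "deleterious_gs":
        return effect.effect == "missense" and effect.deleterious_gs
    return effect.effect == cls


def load_ratio(
    table: GenotypeTable,
    sample: str,
    effects: Sequence[EffectClass],
    ancestral: Sequence[AncestralCall],
    class_filter: str,
) -> float | None:
    """Derived-homozygote load ratio 2H/(2H + X) for one sample and class.

    H counts sites where the sample is homozygous for the derived allele,
    X sites where it is heterozygous, restricted to sites of the requested
    class with a resolved ancestral allele.  Undefined (None) when the
    sample carries no derived allele in the class.
    """
    if class_filter not in CLASSES:
        raise ValueError(f"unknown class {class_filter!r}; expected one of {CLASSES}")
    profile = load_profile(table, sample, effects, ancestral)
    return profile.ratio(class_filter)


def load_profile(
    table: GenotypeTable,
    sample: str,
    effects: Sequence[EffectClass],
    ancestral: Sequence[AncestralCall],
) -> LoadProfile:
    """Per-class derived hom/het counts for one sample."""
    anc_by_site = {c.site_index: c for c in ancestral}
    gt = table.sample_genotypes(sample)
    counts = {cls: [0, 0] for cls in CLASSES}
    for e in effects:
        call = anc_by_site.get(e.site_index)
        if call is None or not call.resolved:
            continue
        dosage = call.derived_dosage(int(gt[e.site_index]))
        if dosage is None:
            continue
        for cls in CLASSES:
            if _class_of(e, cls):
                if dosage == 2:
                    counts[cls][0] += 1
                elif dosage == 1:
                    counts[cls][1] += 1
    return LoadProfile(sample, {k: (v[0], v[1]) for k, v in counts.items()})


def lineage_load_summary(
    profiles: Iterable[LoadProfile], lineages: LineageMap
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-lineage mean load ratios and pairwise Wilcoxon rank-sum tests.

    Returns ``(means, tests)``: means indexed by lineage with one column per
    class; tests with one row per (class, lineage pair) and the rank-sum
    p-value (skipped when either group has fewer than two defined ratios).
    """
    rows = []
    for p in profiles:
        lineage = lineages.lineage_of.get(p.sample)
        if lineage is None:
            raise ValueError(f"sample {p.sample!r} has no lineage label")
        for cls in CLASSES:
            rows.append((lineage, p.sample, cls, p.ratio(cls)))
    df = pd.DataFrame(rows, columns=["lineage", "sample", "class", "ratio"])
    means = df.pivot_table(index="lineage", columns="class", values="ratio",
                           aggfunc="mean")
    tests = []
    lin = sorted(df["lineage"].unique())
    for cls in CLASSES:
        sub = df[df["class"] == cls].dropna(subset=["ratio"])
        for i, a in enumerate(lin):
            for b in lin[i + 1:]:
                ra = sub.loc[sub["lineage"] == a, "ratio"]
                rb = sub.loc[sub["lineage"] == b, "ratio"]
                if len(ra) < 2 or len(rb) < 2:
                    pval = np.nan
                else:
                    pval = sps.ranksums(ra, rb).pvalue
                tests.append((cls, a, b, len(ra), len(rb), pval))
    tests_df = pd.DataFrame(
        tests, columns=["class", "lineage_a", "lineage_b", "n_a", "n_b", "pvalue"]
    )
    return means, tests_df
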