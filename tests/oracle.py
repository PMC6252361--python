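"""Independent brute-force re-implementations of the filtering rules.

Each predicate here is a direct, standalone translation of the stated
filtering rule, written against raw field values (strings and numbers,
no calls into the package's filter or inheritance modules). The tests
compare the package's output against these on synthetic variant sets.
"""

from __future__ import annotations

from itertools import combinations


def oracle_standard_frequency(af_1000g, af_exac, af_evs, max_af=0.005) -> bool:
    """Frequency ≤ max in every database that reports the variant."""
    for af in (af_1000g, af_exac, af_evs):
        if af is not None and af > max_af:
            return False
    return True


def oracle_permissive_frequency(
    af_1000g, af_exac, af_evs, hom_count, hemi_count, on_x_nonpar, max_af=0.10
) -> bool:
    """AF ≤ 10% everywhere reported, no ExAC homozygotes (nor hemizygotes on X)."""
    for af in (af_1000g, af_exac, af_evs):
        if af is not None and af > max_af:
            return False
    if hom_count is not None and hom_count > 0:
        return False
    if on_x_nonpar and hemi_count is not None and hemi_count > 0:
        return False
    return True


DELETERIOUS_CATEGORIES = {
    "snv_deleterious_missense",
    "frameshift",
    "start_lost",
    "stop_gained",
    "stop_lost",
}


def oracle_deleterious(consequence: str, splice_distance, window=7) -> bool:
    """Deleterious categories plus splice-region sites within ±window bp."""
    if consequence in DELETERIOUS_CATEGORIES:
        return True
    if consequence == "splice_region" and splice_distance is not None:
        return abs(splice_distance) <= window
    return False


# --- genotype-configuration truth tables (p, m, f are state strings) ------


def oracle_de_novo(p: str, m: str, f: str) -> bool:
    return p == "het" and m == "hom_ref" and f == "hom_ref"


def oracle_ar_homozygous_autosomal(p: str, m: str, f: str) -> bool:
    return p == "hom_alt" and m == "het" and f == "het"


def oracle_ar_homozygous_x_female(p: str, m: str, f: str) -> bool:
    # female proband on non-PAR X: transmitting father is hemizygous-alt
    return p == "hom_alt" and m == "het" and f == "hemi_alt"


def oracle_x_linked_male(p: str, m: str, f: str) -> bool:
    return p == "hemi_alt" and f == "hom_ref" and m in ("het", "hom_ref")


def oracle_origin(p: str, m: str, f: str, on_x_nonpar: bool) -> str | None:
    """Phase of a proband het: maternal / paternal / unresolved / None."""
    if p != "het" or m == "missing" or f == "missing":
        return None
    mother_carries = m in ("het", "hom_alt")
    father_carries = f == "hemi_alt" if on_x_nonpar else f in ("het", "hom_alt")
    if mother_carries and father_carries:
        return "unresolved"
    if mother_carries:
        return "maternal"
    if father_carries:
        return "paternal"
    return None


def oracle_compound_het_pairs(
    variants: list[tuple[str, str, str, str, bool]]
) -> set[frozenset[str]]:
    """Brute-force trans pairs over (key, p, m, f, on_x_nonpar) tuples."""
    pairs: set[frozenset[str]] = set()
    for (ka, *ga), (kb, *gb) in combinations(variants, 2):
        oa = oracle_origin(ga[0], ga[1], ga[2], ga[3])
        ob = oracle_origin(gb[0], gb[1], gb[2], gb[3])
        if {oa, ob} == {"maternal", "paternal"}:
            pairs.add(frozenset({ka, kb}))
    return pairs


def oracle_variant_predicates(v, on_x_nonpar: bool) -> tuple[bool, bool, bool]:
    """(standard, permissive, deleterious) for an AnnotatedVariant's raw fields."""
    return (
        oracle_standard_frequency(v.af_1000g, v.af_exac, v.af_evs),
        oracle_permissive_frequency(
            v.af_1000g,
            v.af_exac,
            v.af_evs,
            v.exac_hom_count,
            v.exac_hemi_count,
            on_x_nonpar,
        ),
        oracle_deleterious(v.consequence.value, v.splice_distance),
    )


def oracle_genome_wide_calls(
    variants, proband_sex: str, par_end: int = 100_000
) -> set[tuple[str, tuple[str, ...]]]:
    """All (model, variant-key-tuple) calls over a variant list, brute force.

    Eligibility: deleterious and (standard frequency, or permissive for
    the recessive/X models). De novo candidates must pass the standard
    rule. Compound-het pairs require both members eligible under the
    recessive rule and opposite parental origins within one gene.
    """

    def x_nonpar(v) -> bool:
        return v.chrom == "chrX" and v.pos > par_end

    calls: set[tuple[str, tuple[str, ...]]] = set()
    by_gene: dict[str, list] = {}
    for v in variants:
        gt = v.genotypes
        p, m, f = gt.proband.value, gt.mother.value, gt.father.value
        std, perm, dele = oracle_variant_predicates(v, x_nonpar(v))
        if not dele:
            continue
        if std and oracle_de_novo(p, m, f):
            calls.add(("de_novo", (v.key,)))
        if std or perm:
            if x_nonpar(v):
                if proband_sex == "male" and oracle_x_linked_male(p, m, f):
                    calls.add(("x_linked", (v.key,)))
                if proband_sex == "female" and oracle_ar_homozygous_x_female(p, m, f):
                    calls.add(("ar_homozygous", (v.key,)))
            elif oracle_ar_homozygous_autosomal(p, m, f):
                calls.add(("ar_homozygous", (v.key,)))
            if v.gene:
                by_gene.setdefault(v.gene.upper(), []).append(v)
    for gene_variants in by_gene.values():
        tuples = [
            (
                v.key,
                v.genotypes.proband.value,
                v.genotypes.mother.value,
                v.genotypes.father.value,
                x_nonpar(v),
            )
            for v in gene_variants
        ]
        for pair in oracle_compound_het_pairs(tuples):
            calls.add(("ar_compound_het", tuple(sorted(pair))))
    return calls
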