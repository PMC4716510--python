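"""Genotype and allele-frequency I/O plus basic marker QC.

Handles codominant multilocus genotype tables in GenePop and CSV dialects,
computes allele frequencies by direct counting, and provides a Monte-Carlo
exact Hardy-Weinberg test and a Bonferroni helper. Genotypes are unphased:
each is stored as a canonically sorted pair of allele labels.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Locus",
    "AlleleFrequencySet",
    "GenotypeTable",
    "GenePopParseError",
    "read_genepop",
    "write_genepop",
    "read_genotype_csv",
    "write_genotype_csv",
    "read_frequency_csv",
    "write_frequency_csv",
    "allele_frequencies",
    "hwe_test_mc",
    "bonferroni",
    "qc_report",
]

Genotype = tuple  # (allele, allele) sorted, or None for missing


def make_genotype(a, b):
    """Canonical unordered genotype: sorted pair of allele labels."""
    return tuple(sorted((a, b)))


@dataclass(frozen=True)
class Locus:
    """A locus with its allele labels and population allele frequencies."""

    name: str
    alleles: tuple
    freqs: tuple

    def __post_init__(self):
        if len(self.alleles) < 1:
            raise ValueError(f"locus {self.name}: needs at least one allele")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"locus {self.name}: duplicate allele labels")
        if len(self.alleles) != len(self.freqs):
            raise ValueError(f"locus {self.name}: alleles/freqs length mismatch")
        f = np.asarray(self.freqs, dtype=float)
        if np.any(f <= 0):
            raise ValueError(f"locus {self.name}: all frequencies must be > 0")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"locus {self.name}: frequencies sum to {f.sum()}, not 1")

    def freq_of(self, allele) -> float:
        return self.freqs[self.alleles.index(allele)]

    @property
    def freq_map(self) -> dict:
        return dict(zip(self.alleles, self.freqs))


class AlleleFrequencySet:
    """Ordered collection of :class:`Locus`, keyed by locus name."""

    def __init__(self, loci: Iterable[Locus]):
        self.loci = list(loci)
        self._by_name = {l.name: l for l in self.loci}
        if len(self._by_name) != len(self.loci):
            raise ValueError("duplicate locus names")

    def __iter__(self):
        return iter(self.loci)

    def __len__(self):
        return len(self.loci)

    def __getitem__(self, name: str) -> Locus:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list:
        return [l.name for l in self.loci]


@dataclass
class GenotypeTable:
    """Rectangular table of genotypes: individuals x loci.

    ``genotypes[individual][locus_name]`` is a sorted allele pair or None.
    ``populations`` maps individual id -> population label.
    """

    ids: list
    locus_names: list
    genotypes: dict
    populations: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("individual IDs must be unique")
        for ind in self.ids:
            row = self.genotypes[ind]
            if set(row) != set(self.locus_names):
                raise ValueError(f"individual {ind}: genotype row not rectangular")

    def genotype(self, ind, locus):
        return self.genotypes[ind][locus]

    @property
    def population_labels(self) -> list:
        seen = []
        for ind in self.ids:
            p = self.populations.get(ind)
            if p not in seen:
                seen.append(p)
        return seen


class GenePopParseError(ValueError):
    pass


def _parse_genepop_genotype(code: str, width: int, line_no: int):
    if len(code) != 2 * width or not code.isdigit():
        raise GenePopParseError(
            f"line {line_no}: genotype code {code!r} does not match allele width {width}"
        )
    a, b = int(code[:width]), int(code[width:])
    if a == 0 or b == 0:
        return None
    return make_genotype(a, b)


def read_genepop(path) -> GenotypeTable:
    """Read a GenePop file (2- or 3-digit allele codes, auto-detected).

    The all-zero code (``0000``/``000000``) marks a missing genotype; allele
    labels are kept as integer codes. Populations are labelled pop1, pop2, ...
    in file order.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GenePopParseError("line 1: empty file")
    # line 1 is a free-text title; locus names follow, one per line or
    # comma-separated, until the first POP marker
    locus_names: list = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        row = lines[i].strip()
        if not row:
            raise GenePopParseError(f"line {i + 1}: blank line in locus list")
        locus_names.extend(s.strip() for s in row.split(",") if s.strip())
        i += 1
    if i == len(lines):
        raise GenePopParseError(f"line {len(lines)}: no POP separator found")
    if not locus_names:
        raise GenePopParseError("line 2: no locus names before first POP")

    ids, genotypes, populations = [], {}, {}
    pop_idx = 0
    width = None
    for j in range(i, len(lines)):
        row = lines[j].strip()
        if not row:
            continue
        if row.upper() == "POP":
            pop_idx += 1
            continue
        if "," not in row:
            raise GenePopParseError(f"line {j + 1}: expected 'id , genotypes'")
        ind, rest = row.split(",", 1)
        ind = ind.strip()
        codes = rest.split()
        if len(codes) != len(locus_names):
            raise GenePopParseError(
                f"line {j + 1}: {len(codes)} genotypes for {len(locus_names)} loci"
            )
        if width is None and codes:
            n = len(codes[0])
            if n not in (4, 6):
                raise GenePopParseError(
                    f"line {j + 1}: genotype code length {n} (expected 4 or 6 digits)"
                )
            width = n // 2
        if ind in genotypes:
            raise GenePopParseError(f"line {j + 1}: duplicate individual id {ind!r}")
        ids.append(ind)
        genotypes[ind] = {
            loc: _parse_genepop_genotype(code, width, j + 1)
            for loc, code in zip(locus_names, codes)
        }
        populations[ind] = f"pop{pop_idx}"
    if not ids:
        raise GenePopParseError(f"line {len(lines)}: no individuals found")
    return GenotypeTable(ids, locus_names, genotypes, populations)


def write_genepop(table: GenotypeTable, path, title: str = "kindyad export",
                  width: int = 3) -> None:
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for loc in table.locus_names:
            fh.write(loc + "\n")
        last_pop = object()
        for ind in table.ids:
            pop = table.populations.get(ind)
            if pop != last_pop:
                fh.write("POP\n")
                last_pop = pop
            codes = []
            for loc in table.locus_names:
                g = table.genotypes[ind][loc]
                if g is None:
                    codes.append("0" * (2 * width))
                else:
                    codes.append(f"{int(g[0]):0{width}d}{int(g[1]):0{width}d}")
            fh.write(f"{ind} , " + " ".join(codes) + "\n")


def read_genotype_csv(path) -> GenotypeTable:
    """CSV dialect: columns id, population, then one column per locus with
    'a/b' allele pairs; empty cell = missing."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if len(header) < 3 or header[0] != "id" or header[1] != "population":
            raise ValueError("genotype CSV must start with columns id, population")
        locus_names = header[2:]
        ids, genotypes, populations = [], {}, {}
        for row in reader:
            ind = row[0]
            ids.append(ind)
            populations[ind] = row[1]
            g = {}
            for loc, cell in zip(locus_names, row[2:]):
                if cell.strip() == "":
                    g[loc] = None
                else:
                    a, b = cell.split("/")
                    a, b = a.strip(), b.strip()
                    try:
                        a, b = int(a), int(b)
                    except ValueError:
                        pass
                    g[loc] = make_genotype(a, b)
            genotypes[ind] = g
    return GenotypeTable(ids, locus_names, genotypes, populations)


def write_genotype_csv(table: GenotypeTable, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "population"] + list(table.locus_names))
        for ind in table.ids:
            row = [ind, table.populations.get(ind, "")]
            for loc in table.locus_names:
                g = table.genotypes[ind][loc]
                row.append("" if g is None else f"{g[0]}/{g[1]}")
            w.writerow(row)


def read_frequency_csv(path) -> AlleleFrequencySet:
    """CSV columns: locus, allele, freq."""
    per_locus: dict = {}
    order: list = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            name = row["locus"]
            if name not in per_locus:
                per_locus[name] = ([], [])
                order.append(name)
            allele = row["allele"]
            try:
                allele = int(allele)
            except ValueError:
                pass
            per_locus[name][0].append(allele)
            per_locus[name][1].append(float(row["freq"]))
    return AlleleFrequencySet(
        Locus(name, tuple(per_locus[name][0]), tuple(per_locus[name][1]))
        for name in order
    )


def write_frequency_csv(freqs: AlleleFrequencySet, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["locus", "allele", "freq"])
        for locus in freqs:
            for a, p in zip(locus.alleles, locus.freqs):
                w.writerow([locus.name, a, repr(float(p))])


def allele_frequencies(table: GenotypeTable) -> AlleleFrequencySet:
    """Allele frequencies by direct count over non-missing genotypes.

    frequency = allele count / (2 x number of non-missing individuals).
    """
    loci = []
    for loc in table.locus_names:
        counts: dict = {}
        n_typed = 0
        for ind in table.ids:
            g = table.genotypes[ind][loc]
            if g is None:
                continue
            n_typed += 1
            for a in g:
                counts[a] = counts.get(a, 0) + 1
        if n_typed == 0:
            raise ValueError(f"locus {loc}: all genotypes missing")
        alleles = tuple(sorted(counts))
        freqs = tuple(counts[a] / (2 * n_typed) for a in alleles)
        loci.append(Locus(loc, alleles, freqs))
    return AlleleFrequencySet(loci)


def _log_array_prob(genotypes: Sequence[tuple]) -> float:
    """Log conditional probability of a genotype array given allele counts
    (the Guo-Thompson exact-test statistic, up to constants shared by all
    arrays with the same allele counts): proportional to 2^H / prod n_gg!
    where H is the heterozygote count."""
    from collections import Counter

    het = sum(1 for g in genotypes if g[0] != g[1])
    tally = Counter(genotypes)
    # log [ 2^het / prod_g (count_g!) ] — the variable part of the
    # conditional probability; constants cancel in comparisons
    from math import lgamma, log

    return het * log(2.0) - sum(lgamma(c + 1) for c in tally.values())


def hwe_test_mc(table: GenotypeTable, locus: str, n_perm: int = 1000,
                seed: int = 0, statistic: str = "array_prob") -> float:
    """Monte-Carlo exact test for departure from Hardy-Weinberg equilibrium.

    Resamples allele assignments by shuffling the observed allele vector into
    random pairs, conditioning on allele counts. ``statistic`` is either
    ``"array_prob"`` (conditional probability of the genotype array, low
    values extreme — suited to multi-allelic loci) or ``"het_count"``
    (two-sided on the heterozygote count). Returns the add-one Monte-Carlo
    p-value (1 + extreme) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    observed = [table.genotypes[ind][locus] for ind in table.ids
                if table.genotypes[ind][locus] is not None]
    pool = [a for g in observed for a in g]
    if len(set(pool)) < 2:
        raise ValueError(f"locus {locus}: monomorphic, HWE test undefined")
    rng = np.random.default_rng(seed)
    pool = np.asarray(pool)
    n = len(observed)

    if statistic == "array_prob":
        def stat(gens):
            return _log_array_prob(gens)
        obs_stat = stat(observed)
        extreme = 0
        for _ in range(n_perm):
            perm = rng.permutation(pool)
            gens = [make_genotype(perm[2 * i], perm[2 * i + 1]) for i in range(n)]
            if stat(gens) <= obs_stat + 1e-12:
                extreme += 1
    elif statistic == "het_count":
        obs_het = sum(1 for g in observed if g[0] != g[1])
        hets = np.empty(n_perm)
        for b in range(n_perm):
            perm = rng.permutation(pool)
            hets[b] = np.sum(perm[0::2] != perm[1::2])
        # two-sided: deviation from the permutation mean at least as large
        center = hets.mean()
        extreme = int(np.sum(np.abs(hets - center) >= abs(obs_het - center) - 1e-12))
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return (1 + extreme) / (1 + n_perm)


def bonferroni(p_values: Sequence[float]) -> list:
    """Bonferroni adjustment: min(1, p*m), order preserved."""
    p = list(p_values)
    if not p:
        raise ValueError("empty p-value list")
    if any(x < 0 or x > 1 for x in p):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    return [min(1.0, x * m) for x in p]


def qc_report(table: GenotypeTable, hwe_perms: int = 1000, seed: int = 0) -> dict:
    """Per-locus QC: missingness, allele count, HWE Monte-Carlo p, and a
    low-coverage flag for loci with <50% non-missing individuals (flagged,
    never dropped)."""
    report = {}
    hwe_ps = {}
    for loc in table.locus_names:
        typed = [table.genotypes[ind][loc] for ind in table.ids
                 if table.genotypes[ind][loc] is not None]
        n = len(table.ids)
        alleles = sorted({a for g in typed for a in g})
        entry = {
            "n_typed": len(typed),
            "missing_fraction": 1 - len(typed) / n,
            "n_alleles": len(alleles),
            "low_coverage_flag": len(typed) < 0.5 * n,
            "hwe_p": None,
        }
        if len(alleles) >= 2:
            entry["hwe_p"] = hwe_test_mc(table, loc, n_perm=hwe_perms, seed=seed)
            hwe_ps[loc] = entry["hwe_p"]
        report[loc] = entry
    if hwe_ps:
        adjusted = bonferroni(list(hwe_ps.values()))
        for loc, adj in zip(hwe_ps, adjusted):
            report[loc]["hwe_p_bonferroni"] = adj
    return report
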