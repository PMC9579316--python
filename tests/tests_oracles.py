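"""Independent brute-force oracles shared across test modules.

These enumerate probability models directly (no shared code with the
implementations they check).
"""

import itertools


def pe_duo_enum(p):
    """Motherless-duo exclusion power by enumerating HWE child genotypes.

    A random man is excluded iff he carries neither child allele.
    """
    total = 0.0
    for i, j in itertools.product(range(len(p)), repeat=2):
        shared = p[i] + (p[j] if j != i else 0.0)
        total += p[i] * p[j] * (1.0 - shared) ** 2
    return total


def pe_trio_enum(p):
    """Trio exclusion power by enumerating mother, maternal pick and paternal allele.

    Given mother and child, the paternal candidates are the child alleles
    whose partner allele the mother carries; a random man is excluded iff
    he carries none of them.
    """
    k = len(p)
    total = 0.0
    for m1, m2 in itertools.product(range(k), repeat=2):  # ordered mother genotype
        pm = p[m1] * p[m2]
        for m in (m1, m2):  # maternal transmission, 1/2 each
            for f in range(k):  # true paternal allele from the population
                w = pm * 0.5 * p[f]
                child = (m, f)
                mother = (m1, m2)
                cands = set()
                for c, other in ((child[0], child[1]), (child[1], child[0])):
                    if other in mother:
                        cands.add(c)
                total += w * (1.0 - sum(p[c] for c in cands)) ** 2
    return total
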