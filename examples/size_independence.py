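"""Same topology at different sizes gives the same fingerprint.

Cycles of 10 and 100 nodes, and complete graphs of 4 and 20 nodes, are
compared dimension by dimension.  Apart from the characteristic string
length rho7 (which genuinely grows with a cycle) and the density-driven
rho1, the scaled dimensions are identical: the fingerprint describes the
*shape* of a network, not its size.
"""

from ghust import DIMENSION_NAMES, FamilySpec, compute_ghust, generate

c10 = compute_ghust(generate(FamilySpec("cycle", {"n": 10})))
c100 = compute_ghust(generate(FamilySpec("cycle", {"n": 100})))
k4 = compute_ghust(generate(FamilySpec("complete", {"n": 4})))
k20 = compute_ghust(generate(FamilySpec("complete", {"n": 20})))

print(f"{'dim':>6} {'C10':>8} {'C100':>8} {'K4':>8} {'K20':>8}")
for name in DIMENSION_NAMES:
    print(
        f"{name:>6} {float(getattr(c10, name)):>8.4f} {float(getattr(c100, name)):>8.4f}"
        f" {float(getattr(k4, name)):>8.4f} {float(getattr(k20, name)):>8.4f}"
    )
print(
    "\nCycles agree everywhere except rho7 (string length: 0.9 vs 0.99);\n"
    "complete graphs agree on every triangle dimension (rho8, rho10-rho12)\n"
    "while rho1 tracks density and rho9 the growing vertex sharing."
)
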