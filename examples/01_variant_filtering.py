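"""Six-rule somatic variant filtering on the boundary-case table.

Each candidate variant must clear all six evidence rules (tumor VAF > 10%,
normal VAF < 1%, homopolymer < 3, >= 5 alt reads per strand, coverage >
100, protein/splice-altering consequence).  The fixed boundary table holds
one record per rule sitting exactly at the failing side of its threshold.
"""

from methmarker import filter_variants, simulate_variant_boundary_cases

table = simulate_variant_boundary_cases()
retained, decisions = filter_variants(table)

print(f"{'record':28s} {'passed':6s} failed rules")
for d in decisions:
    rules = ", ".join(r.value for r in d.failed_rules) or "-"
    print(f"{d.variant.sample_id:28s} {str(d.passed):6s} {rules}")
print(f"\nretained {len(retained)} of {len(table)} records")
# Only `all_pass` survives: every other record violates exactly the rule
# its name says, which pins the strict/inclusive reading of each threshold.
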