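"""Deterministic gas-phase protonation planning at a target charge.

Enumerates titratable sites for the liraglutide sequence (Lys20 is
acylated, so its amine is not basic) and plans protonation of a small
site fixture at target charge +2 under the tiered rules: accessible
free acids by descending pKa then SASA, then salt-bridged acids by
ascending bridge distance, then buried acids.
"""

from oligogrowth.protonation import TitratableSite, plan_from_sites, titratable_sites_from_sequence

SEQ = "HAEGTFTSDVSSYLEGQAAXEFIAWLVRGRG"  # X marks the acylated lysine (D6M)
sites = titratable_sites_from_sequence(SEQ)
print("liraglutide titratable sites:")
print("  basic :", ", ".join(s.site_id for s in sites if s.kind == "basic_fixed"))
print("  acidic:", ", ".join(s.site_id for s in sites if s.kind == "acidic"))

fixture = [TitratableSite(f"B{i}", "basic_fixed", 10.0, order=i) for i in range(3)] + [
    TitratableSite("GluA", "acidic", 4.25, sasa=120.0, order=3),
    TitratableSite("GluB", "acidic", 4.25, sasa=80.0, order=4),
    TitratableSite("AspD", "acidic", 3.65, sasa=90.0, order=5),
    TitratableSite("AspC", "acidic", 3.65, sasa=100.0, salt_bridge_distance=3.0, order=6),
]
plan = plan_from_sites(fixture, target_charge=2)
print(f"\nfixture: initial charge {plan.initial_charge:+d}, target {plan.target_charge:+d}")
print("protonation order:", " > ".join(s.site_id for s in plan.ordered_sites))
print("protonated       :", ", ".join(s.site_id for s in plan.protonated))
print("\nThe bridged AspC waits behind every accessible free acid even though")
print("its SASA beats AspD's: bridge tier comes after the free tier.")
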