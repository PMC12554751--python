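"""Net charge of antibody CDR sequences at physiological pH.

Positively charged CDRs are associated with nonspecific binding; the
Henderson-Hasselbalch sum over ionizable side chains quantifies this for
any CDR fragment (termini excluded, since CDRs are internal stretches).
"""

from psermkit import ChargeModel, net_charge

hcdr3 = {
    "aducanumab HCDR3": "DRGIGARRGPYYMD",
    "parental clone HCDR3": "DGYDGSYFVGYDYNDFYDY",
}

model = ChargeModel(pH=7.4)
print(f"net charge at pH {model.pH} (side chains only):")
for name, seq in hcdr3.items():
    q = net_charge(seq, model)
    print(f"  {name:>22}: {q:+.2f}   ({seq})")

print("\nthe three arginines make the aducanumab loop positive; the "
      "aspartate-rich parental loop is strongly negative — consistent with "
      "its lower nonspecific binding")

print("\ncharge vs pH for the aducanumab loop:")
for ph in (5.0, 6.0, 7.0, 7.4, 8.0, 9.0):
    q = net_charge(hcdr3["aducanumab HCDR3"], ChargeModel(pH=ph))
    print(f"  pH {ph:>4}: {q:+.2f}")
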