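"""Tentatively assign metabolite compounds to a cultivar's peaks.

Looks up each characteristic peak of White Lion in the bundled reference-band
table: point references match within 3 cm^-1, interval references by
containment. Entries quoted at the same band (1,8-cineol and sabinene, both
652 cm^-1) come back flagged ambiguous.
"""

from chrysoraman import assign_compounds, reference_library

pattern = reference_library()["White Lion"]
print(f"White Lion peaks: {pattern.positions}\n")
print(f"{'peak':>6}  {'compound':<32} {'class':<22} {'dev':>4}  ambiguous")
for a in assign_compounds(pattern):
    ref = f"{a.reference[0]:g}-{a.reference[1]:g}" if isinstance(a.reference, tuple) \
        else f"{a.reference:g}"
    print(f"{a.position:6.0f}  {a.compound:<32} {a.compound_class:<22} "
          f"{a.deviation:4.0f}  {'yes' if a.ambiguous else 'no':>3}   (ref {ref})")
print("\ndev = |peak - reference| cm^-1 for point references (0 inside intervals).")
print("The 1020 cm^-1 peak assigned to crocetin is what sets White Lion apart.")
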