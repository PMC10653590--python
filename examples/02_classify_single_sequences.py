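"""Classify individual OR candidate sequences.

Takes one intact OR coding sequence and applies each pseudogenization
operator in turn, showing how the evidence (premature stop, frameshift,
length, TM count) drives the functional / sub7TM / pseudogene label.
"""
from ormine import classify_status, count_tm_domains, detect_pseudogene_features, simulate

reference = simulate.family_template_cds("4")   # 933 nt incl. stop

cases = {
    "intact": reference,
    "premature stop": simulate.apply_operator(reference, "premature_stop", seed=1),
    "1-nt frameshift": simulate.apply_operator(reference, "frameshift_indel", seed=2, arg=1),
    "in-frame 3-nt indel": simulate.apply_operator(reference, "frameshift_indel", seed=3, arg=3),
    "truncated to 600 nt": simulate.apply_operator(reference, "truncate", seed=4, arg=600),
}

print(f"{'case':>22} {'stop':>6} {'frameshift':>11} {'len':>5} {'TM':>4} {'status':>11}")
for name, seq in cases.items():
    ev = detect_pseudogene_features(seq, reference, "fam4_ref")
    rec = classify_status(name, seq, ev)
    tm = rec.tm_count if rec.tm_count is not None else "-"
    print(f"{name:>22} {str(ev.has_premature_stop):>6} "
          f"{str(ev.has_frameshift):>11} {ev.length_nt:>5} {tm!s:>4} {rec.status:>11}")

# The in-frame indel stays functional (still 7 TM helices, >= 650 nt);
# every other operator flips the sequence to pseudogene. The TM count is
# from a Kyte-Doolittle hydropathy scan of the translation.
topo = count_tm_domains(simulate.planted_helix_protein())
print("\nplanted 7-helix protein ->", topo.tm_count, "predicted TM helices at",
      [f"{s}-{e}" for s, e in topo.helices])
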