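# Carbon-fixation pathway gene lists used to confirm autotrophy.
#
# These are synthetic reconstructions assembled from standard carbon-fixation
# biochemistry (marker = pathway-diagnostic key enzyme subunits; accessory =
# the remaining pathway enzymes). They are placeholders meant to be replaced
# with a project's curated lists; the confirmation rule (>=70% of all genes,
# or all markers plus >50% of accessory genes) does not depend on the exact
# membership.
wood_ljungdahl:
  markers: [acsB, cdhA]
  accessory: [acsC, acsD, acsE, fhs, folD, metF, fdhA, cooS]
calvin_benson_bassham:
  markers: [rbcL]
  accessory: [rbcS, prkB, cbbF, cbbP, cbbA, cbbT, cbbE, cbbG]
reductive_tca:
  markers: [aclA, aclB]
  accessory: [korA, korB, frdA, fumA, mdh, sucC, sucD, porA]
three_hydroxypropionate_bicycle:
  markers: [mct, mch]
  accessory: [accC, accB, pccA, pccB, smtA, smtB, mcl, meh]
three_hp_four_hb:
  markers: [hbsC, hbsT]
  accessory: [accC, accB, msr, scr, hpcd, hbd, abfD, crt]
dicarboxylate_four_hb:
  markers: [hcd, hbcl]
  accessory: [porA, porB, pycA, fumB, frdB, sdhA, abfD, crt]
reverse_glycine_cleavage:
  markers: [gcvP, gcvT]
  accessory: [gcvH, lpd, glyA, sdaA, fhs, folD]
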