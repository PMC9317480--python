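# Default biosynthetic-pathway catalog: riboflavin, biotin, and the ten
# host-essential amino acids, populated from the standard enterobacterial
# (E. coli K-12) biosynthesis gene sets. A step lists alternative genes any
# one of which performs the reaction. Fully overridable by a user catalog
# of the same schema.
pathways:
  riboflavin:
    - {step: ribA, alternatives: [ribA], enzyme: "GTP cyclohydrolase II"}
    - {step: ribD, alternatives: [ribD], enzyme: "diaminohydroxyphosphoribosylaminopyrimidine deaminase/reductase"}
    - {step: phosphatase, alternatives: [yigB, ybjI, yigL], enzyme: "5-amino-6-(5-phospho-D-ribitylamino)uracil phosphatase"}
    - {step: ribB, alternatives: [ribB], enzyme: "3,4-dihydroxy-2-butanone-4-phosphate synthase"}
    - {step: ribH, alternatives: [ribH], enzyme: "6,7-dimethyl-8-ribityllumazine synthase"}
    - {step: ribE, alternatives: [ribE], enzyme: "riboflavin synthase"}
  biotin:
    - {step: bioC, alternatives: [bioC], enzyme: "malonyl-ACP O-methyltransferase"}
    - {step: bioH, alternatives: [bioH], enzyme: "pimeloyl-ACP methyl ester esterase"}
    - {step: bioF, alternatives: [bioF], enzyme: "8-amino-7-oxononanoate synthase"}
    - {step: bioA, alternatives: [bioA], enzyme: "adenosylmethionine-8-amino-7-oxononanoate aminotransferase"}
    - {step: bioD, alternatives: [bioD], enzyme: "dethiobiotin synthetase"}
    - {step: bioB, alternatives: [bioB], enzyme: "biotin synthase"}
  arginine:
    - {step: argA, alternatives: [argA], enzyme: "N-acetylglutamate synthase"}
    - {step: argB, alternatives: [argB], enzyme: "acetylglutamate kinase"}
    - {step: argC, alternatives: [argC], enzyme: "N-acetylglutamylphosphate reductase"}
    - {step: argD, alternatives: [argD], enzyme: "acetylornithine aminotransferase"}
    - {step: argE, alternatives: [argE], enzyme: "acetylornithine deacetylase"}
    - {step: ornithine carbamoyltransferase, alternatives: [argF, argI]}
    - {step: argG, alternatives: [argG], enzyme: "argininosuccinate synthase"}
    - {step: argH, alternatives: [argH], enzyme: "argininosuccinate lyase"}
  histidine:
    - {step: hisG, alternatives: [hisG], enzyme: "ATP phosphoribosyltransferase"}
    - {step: hisI, alternatives: [hisI], enzyme: "phosphoribosyl-AMP cyclohydrolase / phosphoribosyl-ATP pyrophosphatase"}
    - {step: hisA, alternatives: [hisA], enzyme: "ProFAR isomerase"}
    - {step: hisH, alternatives: [hisH], enzyme: "imidazole glycerol phosphate synthase, glutaminase subunit"}
    - {step: hisF, alternatives: [hisF], enzyme: "imidazole glycerol phosphate synthase, cyclase subunit"}
    - {step: hisB, alternatives: [hisB], enzyme: "IGP dehydratase / histidinol-phosphatase"}
    - {step: hisC, alternatives: [hisC], enzyme: "histidinol-phosphate aminotransferase"}
    - {step: hisD, alternatives: [hisD], enzyme: "histidinol dehydrogenase"}
  isoleucine:
    - {step: ilvA, alternatives: [ilvA], enzyme: "threonine deaminase"}
    - {step: acetohydroxyacid synthase, alternatives: [ilvB, ilvI, ilvG]}
    - {step: ilvC, alternatives: [ilvC], enzyme: "ketol-acid reductoisomerase"}
    - {step: ilvD, alternatives: [ilvD], enzyme: "dihydroxyacid dehydratase"}
    - {step: ilvE, alternatives: [ilvE], enzyme: "branched-chain aminotransferase"}
  leucine:
    - {step: leuA, alternatives: [leuA], enzyme: "2-isopropylmalate synthase"}
    - {step: leuC, alternatives: [leuC], enzyme: "isopropylmalate isomerase, large subunit"}
    - {step: leuD, alternatives: [leuD], enzyme: "isopropylmalate isomerase, small subunit"}
    - {step: leuB, alternatives: [leuB], enzyme: "3-isopropylmalate dehydrogenase"}
    - {step: transaminase, alternatives: [ilvE, tyrB]}
  lysine:
    - {step: aspartate kinase, alternatives: [lysC, thrA, metL]}
    - {step: asd, alternatives: [asd], enzyme: "aspartate-semialdehyde dehydrogenase"}
    - {step: dapA, alternatives: [dapA], enzyme: "dihydrodipicolinate synthase"}
    - {step: dapB, alternatives: [dapB], enzyme: "dihydrodipicolinate reductase"}
    - {step: dapD, alternatives: [dapD], enzyme: "tetrahydrodipicolinate succinylase"}
    - {step: succinyldiaminopimelate aminotransferase, alternatives: [dapC, argD]}
    - {step: dapE, alternatives: [dapE], enzyme: "succinyl-diaminopimelate desuccinylase"}
    - {step: dapF, alternatives: [dapF], enzyme: "diaminopimelate epimerase"}
    - {step: lysA, alternatives: [lysA], enzyme: "diaminopimelate decarboxylase"}
  methionine:
    - {step: metA, alternatives: [metA], enzyme: "homoserine O-succinyltransferase"}
    - {step: metB, alternatives: [metB], enzyme: "cystathionine gamma-synthase"}
    - {step: metC, alternatives: [metC], enzyme: "cystathionine beta-lyase"}
    - {step: methionine synthase, alternatives: [metE, metH]}
  phenylalanine:
    - {step: DAHP synthase, alternatives: [aroG, aroF, aroH]}
    - {step: aroB, alternatives: [aroB], enzyme: "dehydroquinate synthase"}
    - {step: aroD, alternatives: [aroD], enzyme: "dehydroquinate dehydratase"}
    - {step: aroE, alternatives: [aroE], enzyme: "shikimate dehydrogenase"}
    - {step: aroK, alternatives: [aroK, aroL], enzyme: "shikimate kinase"}
    - {step: aroA, alternatives: [aroA], enzyme: "EPSP synthase"}
    - {step: aroC, alternatives: [aroC], enzyme: "chorismate synthase"}
    - {step: pheA, alternatives: [pheA], enzyme: "chorismate mutase / prephenate dehydratase"}
    - {step: aminotransferase, alternatives: [tyrB, aspC]}
  threonine:
    - {step: aspartate kinase / homoserine dehydrogenase, alternatives: [thrA, metL]}
    - {step: asd, alternatives: [asd], enzyme: "aspartate-semialdehyde dehydrogenase"}
    - {step: thrB, alternatives: [thrB], enzyme: "homoserine kinase"}
    - {step: thrC, alternatives: [thrC], enzyme: "threonine synthase"}
  tryptophan:
    - {step: trpE, alternatives: [trpE], enzyme: "anthranilate synthase, component I"}
    - {step: trpG, alternatives: [trpG, trpD], enzyme: "anthranilate synthase, component II"}
    - {step: trpD, alternatives: [trpD], enzyme: "anthranilate phosphoribosyltransferase"}
    - {step: trpC, alternatives: [trpC], enzyme: "indole-3-glycerol phosphate synthase"}
    - {step: trpA, alternatives: [trpA], enzyme: "tryptophan synthase, alpha subunit"}
    - {step: trpB, alternatives: [trpB], enzyme: "tryptophan synthase, beta subunit"}
  valine:
    - {step: acetohydroxyacid synthase, alternatives: [ilvB, ilvI, ilvG]}
    - {step: ilvC, alternatives: [ilvC], enzyme: "ketol-acid reductoisomerase"}
    - {step: ilvD, alternatives: [ilvD], enzyme: "dihydroxyacid dehydratase"}
    - {step: ilvE, alternatives: [ilvE], enzyme: "branched-chain aminotransferase"}
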