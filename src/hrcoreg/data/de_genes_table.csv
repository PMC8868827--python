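direction,pathway,gene,symbol_note
up,Apoptosis,BCL2L1,
up,Apoptosis,CASP8,
up,Apoptosis,MYD88,
up,Base excision repair,APEX2,
up,Base excision repair,FEN1,
up,Base excision repair,NEIL3,
up,Base excision repair,PARP1,
up,Base excision repair,SMUG1,
up,Base excision repair,UNG,
up,Base excision repair—Translesion Synthesis—Cell Cycle and Signaling,PCNA,
up,Cell Cycle and Signaling,AURKA,
up,Cell Cycle and Signaling,BUB1B,
up,Cell Cycle and Signaling,CDKN2A,
up,Cell Cycle and Signaling,KRAS,
up,Cell Cycle and Signaling,RAD21,
up,Cell Cycle and Signaling,RM12,printed symbol kept verbatim (HGNC symbol would be RMI2)
up,Cell Cycle and Signaling,SUMO3,
up,Checkpoint Activation,H2AFX,
up,Checkpoint Activation—Cell Cycle and Signaling,CHEK1,expanded from combined entry CHEK1/2
up,Checkpoint Activation—Cell Cycle and Signaling,CHEK2,expanded from combined entry CHEK1/2
up,Homologous Recombination and Fanconi Anemia,BRIP1,
up,Homologous Recombination and Fanconi Anemia,BLM,
up,Homologous Recombination and Fanconi Anemia,BRCA2,
up,Homologous Recombination and Fanconi Anemia,FANCD2,
up,Homologous Recombination and Fanconi Anemia,FANCG,
up,Homologous Recombination and Fanconi Anemia,FANCI,
up,Homologous Recombination and Fanconi Anemia,GEN1,
up,Homologous Recombination and Fanconi Anemia,RAD51,
up,Homologous Recombination and Fanconi Anemia,RAD54L,
up,Homologous Recombination and Fanconi Anemia,UBE2T,
up,Homologous Recombination and Fanconi Anemia,USP1,
up,Homologous Recombination and Fanconi Anemia,XRCC2,
up,Homologous Recombination and Fanconi Anemia,XRCC3,
up,Independent Repair Enzymes/Polymerases,DNA2,
up,Independent Repair Enzymes/Polymerases,POLQ,
up,Independent Repair Enzymes/Polymerases–Base excision repair,POLD1,
up,Independent Repair Enzymes/Polymerases–Base excision repair,POLD4,
up,Independent Repair Enzymes/Polymerases–Base excision repair,POLE2,
up,Independent Repair Enzymes/Polymerases—Cell Cycle and Signaling,MAD2L2,
up,Independent Repair Enzymes/Polymerases–Nucleotide Excision Repair,POLR2D,
up,Independent Repair Enzymes/Polymerases–Nucleotide Excision Repair,POLR2H,
up,Independent Repair Enzymes/Polymerases–Translesion Synthesis,HLTF,
up,Mismatch Repair,MSH2,
up,Mismatch Repair–Translesion Synthesis,RFC4,
up,Non-homologous End Joining—Cell Cycle and Signaling,PRKDC,
up,Translesion Synthesis,RAD18,
up,Housekeeping,SF3FA3,printed symbol kept verbatim (HGNC symbol would be SF3A3)
down,Apoptosis,AKT3,
down,Apoptosis,BCL2,
down,Apoptosis,NFKB2,
down,Apoptosis,PIK3R1,
down,Base Excision Repair,NEIL1,
down,Base Excision Repair,NEIL2,
down,Base Excision Repair,OGG1,
down,Cell Cycle and Signaling,ABL1,
down,Cell Cycle and Signaling,CCND2,
down,Cell Cycle and Signaling,CDKN1A,
down,Cell Cycle and Signaling,EGFR,
down,Checkpoint Activation,TIPIN,
down,Homologous Recombination and Fanconi Anemia,RAD51B,
down,Homologous Recombination and Fanconi Anemia,WRN,
down,Independent Repair Enzymes/Polymerases,ALKBH3,
down,Independent Repair Enzymes/Polymerases,CRY1,
down,Independent Repair Enzymes/Polymerases,POLK,
down,Independent Repair Enzymes/Polymerases,REV1,
down,Independent Repair Enzymes/Polymerases–Translesion Synthesis,POLI,
down,Mismatch Repair,MSH3,
down,Non-homologous End Joining,LIG4,
down,Nucleotide Excision Repair,XPA,
down,Nucleotide Excision Repair—Apoptosis,PTEN,
down,Housekeeping,COG7,
down,Housekeeping,NUBP1,
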