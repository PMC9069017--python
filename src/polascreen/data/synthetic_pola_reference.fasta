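>PolA_Ecoli_K12_synthetic synthetic stand-in for E. coli K12 DNA polymerase I; anchors R688 D705 K758 F762
AISCYLVSMPDLISGQPRFGVAHIFGQAHFGAPYMIQASPHLHRTDTGQVLGMPGERFVF
GQLQGRSGRDGAQANAAPAPTGYKTTLPTTVETHKIALKLDELFAGDSLESFVAYKDQLL
KMCTHLDSTQPEFITYNYKHIPENSPGGECNERPRDLNGKVKLVIAMSQHSQNIVMKPED
RQVVFALLVRDMLAIWVCRVQPTVSGQISRVEQLVYKTLAFAANAGPELQGTISPYSIDH
SNDQRAPETQVDGHDLRSGYMWEQEAMGIAGGHEALDISDADDDQTCHRIGRVQFSPIGR
ASGVNDDESYIDTPDGHYDVVFGETNVRSCVHRVDFNGDVGKPLIIANTIVHINVAFEGE
MISTRINTCISLSKVRFAHDTIVIACDQFPITPTADKKIIKFSSSSFGRLAIADGDEKER
GDYKILFLLERGCLYWVELYFQRVGSADLTGRGAQEITGRPGRKGEGSNSRASATAESKG
SLHVLQQYTPRGPNQYWLSVWESVAIGRLIVTSLLLVEGSIDYTMLLEDDFMGIEYKTEK
VLGLARPKGMVSGTIKKFLSVKPLQRTLLRGPLEASGAIARKTIKNGPLVAVYKIDEVGG
LLVHLKDILDFDAQPLMGFKDPPLLNKFGDDPQSAYGMTMRSTHENPDDAQKRTDKNRAV
WEGRQCFTEVELKPYELKSAGTPKYNFRMLETFINCRCLWGTGSDSLRESGIVCFNLEIV
GDLDPREEFKNTDLKRQDQGGGPFIAIKGYIGNVRSFKQSPFEDRRWAKVVMSIKIAMES
GRGHISNRPLHIDNEKLIAHLLCAALPTDSESTLNKSPKAEGAFVLQLAIICLKSRALAE
VWMDIILASMRAMDLYKSDRGTQVTASPFEHVHFKELLKGYARLAKELLHDHFGDECLGG
GTTRIAANLRLLGCREPSQGAYAQCKKL
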