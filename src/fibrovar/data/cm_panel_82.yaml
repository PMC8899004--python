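# Cardiomyopathy gene panel: 82 genes with established CM associations.
# This list is a user-replaceable compilation (supply your own YAML to
# read_panel_config to change it).  Coordinate windows are approximate
# GRCh37 spans used ONLY to place synthetic variants; they play no role
# in filtering, which is annotation-driven.
maf_threshold: 0.001
cadd_threshold: 20.0
genes:
  "ABCC9":
    chrom: "12"
    window: [199287378, 199550259]
    inheritance: AD
  "ACTC1":
    chrom: "15"
    window: [35080000, 35088000]
    inheritance: AD
  "ACTN2":
    chrom: "1"
    window: [54251282, 54459203]
    inheritance: AD
  "AGL":
    chrom: "1"
    window: [95046417, 95283563]
    inheritance: AR
  "ALMS1":
    chrom: "2"
    window: [39699648, 39900231]
    inheritance: AR
  "ANKRD1":
    chrom: "10"
    window: [173334960, 173632268]
    inheritance: AD
  "BAG3":
    chrom: "10"
    window: [121410000, 121437000]
    inheritance: AD
    lof_mechanism: true
  "CALR3":
    chrom: "19"
    window: [149743223, 149961802]
    inheritance: AR
  "CASQ2":
    chrom: "1"
    window: [175254897, 175405179]
    inheritance: AD
  "CAV3":
    chrom: "3"
    window: [155295991, 155456637]
    inheritance: AD
  "CDH2":
    chrom: "18"
    window: [200625966, 200738875]
    inheritance: AD
  "COX15":
    chrom: "10"
    window: [124512100, 124729126]
    inheritance: AR
  "CRYAB":
    chrom: "11"
    window: [111902000, 111920000]
    inheritance: AD
  "CSRP3":
    chrom: "11"
    window: [120851415, 120885585]
    inheritance: AD
  "CTF1":
    chrom: "16"
    window: [164945247, 164975430]
    inheritance: AD
  "DES":
    chrom: "2"
    window: [220283000, 220291000]
    inheritance: AD
  "DMD":
    chrom: "X"
    window: [31137000, 33229000]
    inheritance: AD
  "DOLK":
    chrom: "9"
    window: [55122277, 55247060]
    inheritance: AR
  "DSC2":
    chrom: "18"
    window: [28645000, 28682000]
    inheritance: AD
    lof_mechanism: true
  "DSG2":
    chrom: "18"
    window: [29078000, 29128000]
    inheritance: AD
    lof_mechanism: true
  "DSP":
    chrom: "6"
    window: [7541000, 7586000]
    inheritance: AD
    lof_mechanism: true
  "DTNA":
    chrom: "18"
    window: [108745896, 108958565]
    inheritance: AD
  "EMD":
    chrom: "X"
    window: [153607000, 153611000]
    inheritance: AD
  "EYA4":
    chrom: "6"
    window: [185647919, 185668642]
    inheritance: AD
  "FHL1":
    chrom: "X"
    window: [135229000, 135294000]
    inheritance: AD
  "FHL2":
    chrom: "2"
    window: [130051527, 130224351]
    inheritance: AD
  "FKRP":
    chrom: "19"
    window: [232137963, 232318403]
    inheritance: AR
  "FKTN":
    chrom: "9"
    window: [189672587, 189693498]
    inheritance: AR
  "FLNC":
    chrom: "7"
    window: [128470000, 128499000]
    inheritance: AD
    lof_mechanism: true
  "GAA":
    chrom: "17"
    window: [78075000, 78094000]
    inheritance: AR
  "GATA4":
    chrom: "8"
    window: [176169009, 176304474]
    inheritance: AD
  "GATA6":
    chrom: "18"
    window: [232442739, 232578630]
    inheritance: AD
  "GATAD1":
    chrom: "7"
    window: [171754751, 171784983]
    inheritance: AD
  "GLA":
    chrom: "X"
    window: [100652000, 100663000]
    inheritance: AD
  "ILK":
    chrom: "11"
    window: [161472358, 161756806]
    inheritance: AD
  "JPH2":
    chrom: "20"
    window: [154925829, 155167178]
    inheritance: AD
  "JUP":
    chrom: "17"
    window: [39910000, 39942000]
    inheritance: AD
  "LAMA4":
    chrom: "6"
    window: [28801666, 28820736]
    inheritance: AD
  "LAMP2":
    chrom: "X"
    window: [119560000, 119603000]
    inheritance: AD
  "LDB3":
    chrom: "10"
    window: [115388588, 115578790]
    inheritance: AD
  "LMNA":
    chrom: "1"
    window: [156052000, 156110000]
    inheritance: AD
    lof_mechanism: true
  "LRRC10":
    chrom: "12"
    window: [239064049, 239245042]
    inheritance: AD
  "MIB1":
    chrom: "18"
    window: [160093203, 160114166]
    inheritance: AD
  "MYBPC3":
    chrom: "11"
    window: [47330000, 47380000]
    inheritance: AD
    lof_mechanism: true
  "MYH6":
    chrom: "14"
    window: [146566510, 146591705]
    inheritance: AD
  "MYH7":
    chrom: "14"
    window: [23412740, 23435660]
    inheritance: AD
  "MYL2":
    chrom: "12"
    window: [110905000, 110925000]
    inheritance: AD
  "MYL3":
    chrom: "3"
    window: [46899000, 46905000]
    inheritance: AD
  "MYLK2":
    chrom: "20"
    window: [127939007, 127998404]
    inheritance: AD
  "MYOZ2":
    chrom: "4"
    window: [45405370, 45456645]
    inheritance: AD
  "MYPN":
    chrom: "10"
    window: [190523961, 190627929]
    inheritance: AD
  "NEXN":
    chrom: "1"
    window: [2760684, 2912905]
    inheritance: AD
  "NKX2-5":
    chrom: "5"
    window: [86536687, 86728652]
    inheritance: AD
  "PDLIM3":
    chrom: "4"
    window: [46420795, 46520275]
    inheritance: AD
  "PKP2":
    chrom: "12"
    window: [32943000, 33049000]
    inheritance: AD
    lof_mechanism: true
  "PLN":
    chrom: "6"
    window: [118869000, 118881000]
    inheritance: AD
  "PRDM16":
    chrom: "1"
    window: [144321591, 144563530]
    inheritance: AD
  "PRKAG2":
    chrom: "7"
    window: [151253000, 151575000]
    inheritance: AD
  "PSEN1":
    chrom: "14"
    window: [64255591, 64348945]
    inheritance: AD
  "PSEN2":
    chrom: "1"
    window: [78913969, 79071307]
    inheritance: AD
  "RBM20":
    chrom: "10"
    window: [112404000, 112599000]
    inheritance: AD
    lof_mechanism: true
  "RYR2":
    chrom: "1"
    window: [237205000, 237997000]
    inheritance: AD
  "SCN5A":
    chrom: "3"
    window: [38589552, 38691164]
    inheritance: AD
  "SCO2":
    chrom: "22"
    window: [3960237, 4050776]
    inheritance: AR
  "SDHA":
    chrom: "5"
    window: [48312925, 48488722]
    inheritance: AD
  "SGCD":
    chrom: "5"
    window: [87270376, 87342661]
    inheritance: AD
  "SLC25A4":
    chrom: "4"
    window: [100306594, 100503996]
    inheritance: AD
  "SYNE1":
    chrom: "6"
    window: [231252303, 231288058]
    inheritance: AD
  "SYNE2":
    chrom: "14"
    window: [38010862, 38199447]
    inheritance: AD
  "TAZ":
    chrom: "X"
    window: [153639000, 153650000]
    inheritance: AD
  "TBX20":
    chrom: "7"
    window: [95614371, 95788023]
    inheritance: AD
  "TCAP":
    chrom: "17"
    window: [122161331, 122330229]
    inheritance: AD
  "TMEM43":
    chrom: "3"
    window: [14166000, 14185000]
    inheritance: AD
    lof_mechanism: true
  "TMPO":
    chrom: "12"
    window: [199666072, 199871676]
    inheritance: AD
  "TNNC1":
    chrom: "3"
    window: [6565186, 6664987]
    inheritance: AD
  "TNNI3":
    chrom: "19"
    window: [55663000, 55670000]
    inheritance: AD
  "TNNT2":
    chrom: "1"
    window: [201328000, 201372000]
    inheritance: AD
  "TPM1":
    chrom: "15"
    window: [63334000, 63365000]
    inheritance: AD
  "TRIM63":
    chrom: "1"
    window: [121550333, 121722395]
    inheritance: AD
  "TTN":
    chrom: "2"
    window: [179390000, 179700000]
    inheritance: AD
    lof_mechanism: true
  "TTR":
    chrom: "18"
    window: [29171000, 29178000]
    inheritance: AD
  "VCL":
    chrom: "10"
    window: [159967984, 160259779]
    inheritance: AD
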