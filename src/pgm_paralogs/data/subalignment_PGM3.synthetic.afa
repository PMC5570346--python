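>PGM3|adjusted
ERYWTKTYEPIDHLICWGKASQGVCASKIFLSSAPRSDEPR-------------------
-------------------------------------GPAGMPGISLVPTPFAIKANDIN
DIALITESTFLSSPEKFPDKEWYAIHIELARYKLEELPYVREDEEDAESGPATASHN--P
AG---AAWYVDELPKILSL--------------VYVPIAGDSASSYALMTNWIHKRWPYH
KFVVRFTALPKVLFTIIGHSAFTIPNDGVGTKHPWNAATLARESVILIHLSDLGTQGLSE
ESNLHGINDLMGADSLRPPPN--------------ASLKLQILLFLEWTTTAVSTTQNRA
EDGDADRGLRHAPADTLVDAWRAMQD--------VLKDFTKTAPLEDIPTSYTFQVWLIY
AGVVFLLEDLPATIYPKHAPPSKCEDELCVPPKFIPTQQWQDRPYFEAN----SINWAFF
PPQLRRSFRSAKRGHFEPGPLASVGMPKRIIVVLTDKPSSGKVKLRYTVTLIGADISGPL
AIYNNLNYNELQ---LTTLKGITLKSNEWSLEEMVWRHATGWGDICMAVIDTDTRRLSHR
SGTAE---DAKRRSQKLGAELPTGTLQSSPYQELKQGFYEDLWLALTMI----------
>PGM3_rel1|adjusted
ERYQTKTYAPIDHLDRQGKRSQGVCATKIFLISASKSDEPR-------------------
-------------------------------------TPDRMPFFSAVPTPSAFKKNDIN
DFELITESIGLGSPEKFPDREHYAIHEEAADYVLEELPYSRHDADDSEVGPLTASHN--P
AG---TAFYNEELPKSLSL--------------PYVDREGDSASLYALMFNMIHKRWPYH
LFVPKFTALPKLLFIIIGHSAFTIPFDGTGTRAPSNMATLAAESVIAVHLSGLGLFGLVE
RSNLAGINDLMGADSLRPPPN--------------QSQKLQILCGLYWTVTYVSTTCNKA
ADGDADRGLPHAPAAYQVDAHRAMQD--------VLKDTFVTAPLEDIPTSYTFVVHLIS
AGVNGLLEEGPELVYPKPAPPSKAEDALFVPPIFFPTQQRQDRPYFEAN----KINFVAF
PPLLKHSFKSEKIGAFAPGPLASVGMPKKDPEGASDKPSSGLLKLRQTVSLRGLVTYGPL
AIYNNLVYNELQ---LTTLKGITLASAAVSAEEMVLRHHTAWGDICMKVIDTDTGKLSSR
SGTAE---DAKRRSEELGLECPTGTWPSYPYQEQKQRFYVDLRSILDMV----------
>PGM3_rel2|adjusted
FRYATKTYEPVVLLICLRKASQGVLGPKIFQSSAPRSDEPR-------------------
-------------------------------------LGAGMPGYVKVPTGFAIKAIDIN
DMILMTERTGLSSNEKIPDKDWYREHIILHIYRLEELPEVCADEADAESGPATASHN--P
AG---AARYVIELPKYRTL--------------VMVPIAGDSLTSYELMTNWIHKNWPYH
KFVVNTTALPKRQNTIIGDSAFTIPNDGVGTKGPLGLASLAGESVFSEHLSDAGTQGLSE
ASNLHNINDLIGGDYLRPPPN--------------AVWKFLVALFLEPTTTLNSTTCPIA
EDGDADRGLISAPADTLVDAYKAMQD--------VSKDGTKTAPACDWPSSSTHQVWHVR
AGGVFLSEDQSAHISPKHFPPSKLEDELFVPPKFIPTQQRQDRPYFEAN----SRNWAFF
PPTQGRSFRSANRGAFTPGPADSVRMPKRIIVVTTSWPSSIKNILRYTTTLIGARISGPL
AVYNNYNYNPLQ---YHTLKAIRLKSREWSMVETVWRHATGPGDIIMLIIDTDDKKLKHR
SGTAE---DAKRKPQKLVAELQTGTLDMSPYQELRQFGYEVQWLAETEI----------
>PGM3_rel3|adjusted
ESYWTDTYEPIDHLILWGKASQGVCHSWVTLSSRPKYEIPR-------------------
-------------------------------------GPARMPGWSLVPVPFKIDVVDGM
DIRLETASSGLSSPERFPDKEWYEILEELARYKTEELPTVRPDEEDAICEPLTASHN--P
AG---AAHYVDELPKRLSL--------------VWVPQEGESASHYRLMTNQCHKGWPYH
KTVVRIRALPKVAITIIGPSAATEPNDYVGTKHPWNEATLNRESVRLIDLSIEGTQGLSF
ESNHKFFNDLMREDTLRPMPN--------------ASLKLQNLLFLEHTTTAVSTSQRRA
EDGDADRGLIAAPGDTRVDAWRLMWD--------LLAIGTKTAPWEDKPTVVTFQVWLIY
AGVNFLLEDLPGTIYPRHLMPSKLETELCVPPRGIPSQQKQKKPYFEAN----SINWYFF
PPCLGRPIRSAKGGHIEPGPLAVIGMPKRIIRGLTDKPSSGRVRARYTATLIGCRISGPL
AIYNNCNYNELQ---LTTTWIITLKSNDWTLAEMVWRHATGLGFISGLVIQTDTRRLTHR
SGTAE---DAKRRSQKLGMELPIGTLISSPYQELWQGYYEDLWLARTMR----------
>PGM3_rel4|adjusted
EGSWSKTQEPRDHLICCDKADNGVVASRIILSTAPASPEPR-------------------
-------------------------------------GQAGMPARSLVPTPFAILANEIN
DIALVTESFLNSSPERFPDKEASEIHFELIRSKLAWAPYVREDEEDAESGPATASHN--P
AG---HAWYVDELPKRLLL--------------VYVAEATDSASSYASMTNWFAWRWPYH
KTVAWFTAAPKVLTTEIGWLAEFAPNDGNDTKHPWVAATLARAPMVLVHLSDLGTLGASE
EWNCHAINAAMGEDSKRPPPN--------------ASLGLQILHFLFWVTTEVSTSQNKA
EDGDADRDLRHAPADTLIDALRAMQD--------FLKSFTKTRPLEDRVNSYTWQVDLID
EGVVFLLEDQPAFVYAKALPPSKCEDETLVPPNTVPTQQWQPKSYFEAN----PINWAFF
PPQLRRSIRVKKRGHGEPDPSASVGMPKIIRVKLSPKPESGKQKLKYLVELIGEDISASR
LIYNALNYNELQ---ATTLGGITLKINAWSLESYEWKWATGWKDEVPAVLITDTRRLSAR
SGTAE---DAKRNSQKLGETLPTYSCNSSPYQELDQENYDDLWLELFMF----------
>PGM3_rel5|adjusted
ERYYSFDYEPKDALFCRGKGSQRICASKIGLSSWPKSPEPR-------------------
-------------------------------------GPEGIPGISLVPSPFGIVENDPK
GIAAETESTFLSSPEIGYDKEKYAFAFELAGYRLAILPYVKEDEETTESGPATASHN--P
AG---RAWYVEELPKVLYL--------------VYVPITGDSHSSYALMTNHIAKRWPSH
KFVVRETEGPKILATVIFHSAFLRPKDGVGFKHWQNAAILARESVIAIHLSDAETIGLSE
EGNVTGVNDDMGEDELHDPPN--------------ASLEQQIRLFLEKTTTAISEPDNWA
IDGDADRFLIHAPADTLVDGWRAHQD--------VAKVFTKTCPLEDIPTSATQLVWLRY
HFVVFLLEDLPATIYPKHLPPPKQADELCVPPKFFPFQQLDDRPYFEAN----SENWAFF
PPQLNRSFRSERRGHFEMGEVGYVGMPRRIVVVLRDLPSSLKQRLKYTVTDIATSFSGPG
VIYNGLVYNELQ---LTTLRGETWKSDEWSLEEMNWRNATGEGDIGMANIDTDTRRLSER
SGTAE---DAKRRSRKLRAEAPDGTLQSSPYWELKQRFYDDLRLALTMI----------
>PGM3_rel6|adjusted
EGYLSKTYAPIDHKICWGRASQGVCANKIFASTAPRSHESR-------------------
-------------------------------------GPAGMPGILLVPKPIAINANDEN
DIALVFEYTFLSSPCRTYDKEHYLYAIELERAKLTLLMYVRVDELDEEVLPGTASHN--P
AG---ELWYVDEGVKILSL--------------VFVPDAGQSAESYALMSNWREKYWPHH
KFIVLFTELPTVLNTIIGHSEITGPNDGVGWKAPWNAATQAGEKVVGVHLSDLGTEALYA
ESNLAGFAELMDADSWRPPPN--------------AVAKLQTLLFLEWTTSAVSLIDNRA
EDGDADRGFRHAPADTLVDAQRHMED--------VSKDFYKTAGLEVIPTISTFQIWLIH
WGVVVLLEDLPTTIYPKHAPPKKGEGGLNIPPKFIPTQQHLDKPYFEAN----SVNHRFF
PPLQKRSFRSAKRGEFEPAPLAYIGMPTRGILVLTDKTSSGRVALGYTSTWIGADIVGPA
RNIRNANSNVLQ---WTTLKGFIAKSNEWSLMEMVYRHATGWGDVCMAVDDTGTDRKSHR
SGTAE---DAKRRTVRDEAELPTGTPLYSPYQAAKQGTYEDLHLELTMT----------
>PGM3_rel7|adjusted
EFYRTKSYIPIDHANCWGKYGQGVGASREKLSSAPRVDDSR-------------------
-------------------------------------SPAGMPGISLVPIPWAIKYNPDP
DVLLITISVFWSSPYKGGDKEWYAIWIELARLRLAALPLVRGNEDDCCSMMWTASHN--P
AG---EERYIDILPNRAPL--------------EYIWVEGDSFSSYACMTNWIHKRKPYH
KFVVKFTALPKVLFVTEGHSLPTAPNDGWGTHHPFVAAPLIRISVIHIILSILGTQGLSE
DSNLDGGNDLMGADSLNPHPN--------------ASWMLQRLLFLEWTTSAVSTVQPRH
EDGDADRGFRHAPADTLVPLWIAMQD--------VLGDQTKFAPAFQEPTSYTFQVWLIA
ARPSTLLADLPATIAPRTRPPSKCEDELCVMTKNIPTQQILDRPYFEAN----SINWFFF
PPLLRRSGISAKRGHTDPGMLYSGEMPKRIILSLTDDPYSFRVKLRYKITLIQADEVGEL
AIVNNLNSNELQ---LTSFKGITLKSNTKSLEEMVWNHHTAWLKIGMHRVDFDFGALSWR
SGTAE---DAKRRIQKLGLELATKTLQSSPYQALRQGMYEGLKGEGTMF----------
>PGM3_rel8|adjusted
ERSWLKTAEPIDHLIDWGKYSQGVCALKIFNSSAPGSQEPR-------------------
-------------------------------------GEEGMPGGSLVPTPNAIKENDIN
DIHLITASHFLPSPCKFPDKELYAFHIGLARAKLEHLPYFKEDQKDAISGNATASHN--P
AG---CEWQVDELPLIASL--------------VYVPVDGRSASSAASMTVWIHKRHPMH
KTSVRFTCLPKVLFFIIGESAFTVMFDGCATKHPWNHASLAAYSVILFHLSDLGTQGLSD
CSVIAGINDLMGADSLRPPPN--------------YSLKLQRNLMLEWTTTAVSTTQNRA
LDGDADRGLGHAPADFLNDAWRAMQD--------QLRDETKTASAEDRPTSYTFQVSLAY
AGVVGKLEGLPATIYPEHEPPGRCAEELCVPPVIKPTQQQLDRPYFEAN----PQFRAGF
PPHLKWSFRGAKRGAFEPGPLRSSGMPRRIIRVLTDKPTSGKVKLRYTVTTRQADISLPL
LIYNNGNYNRLQ---LTFLNGITLRDNERSLEEYVWIHATGWRVICMAFIDSTTDIKIPR
SGTAE---DAKRRSQKLGEALPTGACQSSPYQELKQGFYFDLWAALRGI----------
>PGM3_rel9|adjusted
ERYLFKTYEPIDAPFCWGKASFGICYSLYFQSFAPRPDEPR-------------------
-------------------------------------GPLGPSGSSLVATPFLIKANDVN
DRAEKTESTFLSSPARFPEREAYPRHFELLRYKLIELPYVREQEEDAESGPITASHN--P
AG---AAWYVDDLPWILSL--------------KYVPIAAASESSYALMFIWIHERKPSH
IIVLKFVADPKVLFLVNAHSAFTDPNDGRGTKRPFNGARLAREDVRLVHLSDAGTLGLSE
ESNLHGINDLMGADSCKPPTN--------------ASLKCQRRAFLEHYATAVSGTQNIA
EDGDADRNWRWANALLQVDGWIHMQD--------VAKDFTRTYPGNDFPVSSSFFVRLKY
KGIVILQEELPLDIYPWHAPPSRAEDEAVNPPVITPEQQWQEGPYFEAN----SINWLFF
PPQLRKSFRSGWGGHFEPGPLASDGMPKRKIGVLTDKPSSGDVRLKYFVTLIGRDSSGPG
LRYGNLNYNELQ---KTTLRGITARSGIKKLEEGVWSHATTNGDDAWLVIDTDTRRCSHR
SGTAE---DAKRRSQKGGHELPTASLQSSPQQAEEQGIYEDLWLAATMH----------
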