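>PGM1|PGM1
---WTLLSFRAPALVCLIMAPTTRVLLKGSTVTAPKSLRNN-------------------
------------------------------------GPQWPYPGASLNSLAEGEKAITND
FAQLIAHTSNGSVMPGQSRIESEENHCELEASIEAVIEYVDAPKSDEPSGSLTASHN--P
GGPLLLSAGSEELFKVLLAGGGAVTDFAHICPGNSVRNGKADSVGHHTAAVQEAKCSIQL
KNVCAGSMQEVNHGSCVALHYTARIIFQVIISEPTRWTPVENTGVVQTHGPNGFAPSHSA
LSVLLVVGGLRDAEGSVPIVH--------------LDWASAGADCGRRTSTRASTTEGAK
QDGDGDRLAMELPEPTIID----------------HLIKIKSALNKSRVFRGNYQIILVG
TGSGRPTRKWVGLIAPSVTPLNDRDTETGSLRAKGPSDQHLNATGEESFGVKI--DAKEE
PLCLRINEGSIGEERDSAEPIDSVNELRKRNQLR-----PQLVRIIYNIEKGDRGISANS
SIYNDYVLFRDNYLYLHTLFLLRVKSTAISRFLYMRNALHFAVLITPVVVEDEMGEGSDR
GSGTGKVGSKARLPKRQVLIAFEGFLTPVTFQEGNTEFNPECRTEQDETGVLDSKLKDF
>PGM2|PGM2
-------------LIGLRMEPVVLTWGKITGFSPPQTLRPPTGDSGPCIGCCGKCLDDKQ
KAAVTRMGGCFQSENIVGYAFFTNPEESYVGLLVGLAPVAAYPAAVLDSLAMMLRSGTNP
LIDLIQASYEDLTMVQNCRRENFANDTEQYDPMIEEGAQVGEIREDEHSTSLTASHNSHG
GA-CYKPIGEGGLPKSLQT-----------------PGEGQTGSLHAAATIMLAKDAHQL
KSIGGTSMQGAVHVYQRGIPYHHQVLTQVEVNGTVAQQELEWGGVICHAAWCGDSDWASV
RGTWDVEAALIDANGLVPVLL---------KISSIKNWYYVLGANIDWTSLTHSTTAGLQ
LDPDADRGDMNEPELTYEDRDAVMCYEQLEEFMRKKLDLVKVGANVPGNGSAGSQIEWKE
ERSAKRPFPLVKACAGIIEPCSDLGTRTFSAGLRDTKDSAHVFAFEE--GTYGYEDHETS
VLLCSGVYISGGDEPDDPFPNNPVIDLKRIVVFLFTDYSPLQNWFRYFVEYDYDDISGPV
WTANDLNANTLNFLLCVSLDGNNVKETERSEIHNIIQALNIEVLIDPENQYFATRQLLLR
SGTPEKLKASRNTHIRLNLELDSLYLQVRSKFFVKFFFLPFSKTECPFKGKVKF-----
>PGM2L1|PGM2L1
EAVVQQTSQATPALIGCRMIPCVLQYGKITGFSPSDTLAPPTGDSGLGAGALGFALDDKG
KAAITRALVCKLSENVIGSAIFSGPEESSVGLLNGLAPVALYPAALLNSKDIWLISGTNP
LFGLQVASYNGLFMVDFCRREFTAAGTICYTSMISIGAYGGEPVADDASTSLTASHNRKE
-RPCYKPECRDGLPKSLQS-----------------------------YTVGLLRMLHRL
KSVGGQSMQRAVDISQIGDPSGLRNATQEGVNDTTAQQELIWDSVVQDLAAEGVSDRFVF
CVFSDVTAGTGDANGAVPVKQNDVSNEIPFKKSGIKDWYIVQLENLDWVSLTHSTHEGCQ
LDPDADR--MYDPELTYVVRDAVMCMAQLCEVRRLLGDLCNQEANRSGVGSAGYLILCKE
EGSIKAPGPLTIANAGIFIPRIDLETRTGSAGLRYSHETAGLFAFEESIEIYGSEDTASP
NLCLRITYKVGGEEPEDPQPVNSVIKKLDTVLTATADKSPLVPGFKYTVEYIYDDPTGPV
IFANDANSNTLCFCLLETLMFVKVKSIDGSHIAMVITAGFGEVLIEPENQQSATRQLLDR
SGGTEPKKASRNLPKIANAILESHILQVPSDIGNTSFALPFGKTAQPQVGSVGF-----
>PGM3|PGM3|adjusted
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
>PGM5|PGM5
-------------------------------------------------------TDDKD
SMELTADIIQDQSENNVGYARISGPIEPPVDQHIGSCPVHASPGESLNSKAEGVRDITNV
FALCIAATSNEYVMFLQSKIETVANHQEGIMSREHVLAYVLEPKAMEASFSKTASHN--P
GGPCILSAGSELLPKVLQSLGGAITGFADECPCNYVADRKASSSGHHTATVQQAKLYEQL
KNVLAGSMQHNNPGSCKLLPYTYKIITQVSINEPDAGLALANESIVQTYAMATGAPWHPI
ASNLLVVGAQRDAEGSVNIVD------------SRRMIAYVFAECCIHTSTRASTFFEKL
LDGDGDR------------------YHQLLEVAKEALVLVKTHLNKSGKLRGVYQAFAVV
TGSRKHSIKWVGLVAPSVCPFSDWETDQGPLRLKGRSDDHLDESGEESFSVYTSVAAKFP
SAQLDIVDYPRGEIIEFAAPRISVRALIRKDQTR-----PQVNRFAYTIERFDIEASEPS
TDYNDLVLFFLNMLATHTLRLRKVKPTARVYFLYVQVAQEIAALRTFVNLEIAFWELSDR
GSGTSGARVGIRKDRRLDLIIQEGQLTSRIFLSGVRGFNPFLGTAQPAIGILDFKLRGI
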