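>PGM2L1
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
>PGM2L1_rel1
ELVFLVTSRATPALPSAIMIPCVLLYGKRTDTSPSDTLAAPFEDSGLIAGALGNALDDKG
KAEITKALIAKFTENRIGSEDISGPEESVVDKLVRTYPSALYPGLLLNSKFKWLITGTNP
LIGLLVMSYNGQFMVVFCRREFTHAGTECYTSMPSIGEMEGEPVAAFASLSLTASHNRKE
-RPQYKVEVRDGTLKSLLS-----------------------------YTVDLCRMLWGL
KGVARLSGQWAVNVSLFGEPSFARNAFQESINKTRAQQELIWDSNVRNAAAEGVSDKFVF
LVFYPITALTGDANGLIPNKQNDVSNEIPARKSGFRDWYFNQLENLDRWSGTHVTIHGCQ
NDPDADR--MYDPECEYIVGDAVMCMAEKQEVWRTLGALFVQEAIKSGVTSYGYLQLAKE
EGSIKAPGPLTFENAGITPPIVTLEFRTGPIGWRYSHETGGCFAFEESIEIYGSAEIHSP
NLCCRITYLLGGEIPAAPQPAVSFHKKLDTVLTATLAKSPLVPGFLYYVEKEVDDPVGGV
EFADDLVSNTLCFNLAETLMVCKIASVDFSHSAMVVIDGFCEVLIASEVQYSAKRNLLDR
SGGTEPKDAPKKLPKILQAILDSHILQIPSDNGNTSTALPFGKTAAPQVDLVGT-----
>PGM2L1_rel2
EAPVCIVSQATPELFGVRMIPCVLQMAKITATSPSDTTAPPKGDSDLGAGLAGYALDDKG
QAAFTIALFCRLSGNVFGTACFSGYEESSIGLLNGLMPVALYPLALLNSTDIWLISATNP
LFGLIVASYNGLFMVDFGNLDFTACGTICYTSMISIDAYGGENDIDFAETTKTASHNRKE
-LDCYPNELQIFHPASQNS-----------------------------YTVGLLRFLHRF
RSVGGQNMKRALVIYQIGDTYALIVATGAGSNVTTALVELIWDSIVQDKGQEGVSDRTVF
AVFSDVFAGTGDAVCLVPVKQNDVCNAKPIRISGIKRWYTVQWENLDWISLTHSTHEGCQ
VDPDADR--MYQPELTANNRDANMGMAQLCDQRRQTGDLVTQRLNISFIKSHGYLILAKE
EFSDKAPGPPTVANAGGFISNFDDETITGSAGLRSSHEGAGCFAFEESIEIYGSIVTGSP
NACDRITYKTGGEKPADPQPVNSIFKKKVTNLSATADKSPLVPGFKYTVWYPYDDPTGPR
IEANDENSNWLCFVQLETLMGVLVRSIDGSRIYMNQKAGTGAVLEEPENQIPAIRQLLDR
SGGTEPKKAQRNLPKIANLVLESHALCVNSDFCNTVIHLPEGKTAYPQCPSIGG-----
>PGM2L1_rel3
IELFQQTSGAFCAPFGQIMIPCVFQAGKVTKISMSATAAPPTGDSGLGHGALGFALDDKV
KHAITAALDFKCSEGVIGSAVTSGSAASSVGLAFGLAPVALYPWACLNSKDVWCISGTNP
LTGLQVLSYNGAIMVDFCTREQTARGTICATSMISIGAMGGEPINDDASTSLTASHNRKE
-RPCYKPECDEGLPKSLQM-----------------------------YTVGFLRMAADL
KSVAGQSYQRENDVSQVDDASGLKNATQEGVNDTTAQIILIWGSVVQKLEAEQVSWRPPN
CVGSDVTAGEFDAVGALPVKQNDVSNEEPPKISGRKEWYIVQLENADWISQTHSTHLGVQ
LDPDADR--YYRPILIHRVPDFVMCMEQGREDRGLLLDNANQEANRSGVGSAGDFILFNE
EGSIKEPGPWKIAKLGIIIPRIGLDIRTGPAGLWYSHETAGLFAFEESIAIYGDLDTASP
WLSWGATYKKGGEEPEDPTPVNWCIKKLTTVLTETADTTPCVPGFKYTVEYAYDFPGGPV
ITANLAQSVTLCFCLLATAMFLKVKSRQLSHIHMNDVAGLGPVLIAPENQQSATDQSQER
SGGTEPKKESRNLPKFYNTGLESHILIVPIDIGNLYNALNFEKIAQPLVGSVDF-----
>PGM2L1_rel4
EAVVSQTSADTEILTGLGMIPCVLQYGTRTGFSPSDILAPPTDDSGLCAGALGFALDDKG
RALRTRALVRELTENCTASEIFTGPEEVTNFLLVGLAPVASYPAALLNYKDFHLINFTPP
GIGGQIASYNGLFMVDTTRREFTAAFTGAYTSMDDRGAYGGEPVQDDASTPLTASHNRKE
-GPCYVPACRDGTPKGLQS-----------------------------YSSGKRWMLQRL
KTVGGQSMAKLVDVSQENDPSGLRNATVIGVNDLTAQQEGIWDSVNFDLEYEGTSDNFVG
CVFSDVTAGTGDANGAIPVKQNDVSNAISMKKSAIKDAYIVQGERLDWNSLTHVTAAGCQ
ADPDADR--MYDPELTYLVRDAVMVMAQEHEVCRLLGEWQNQEANRTDSGSNSYWILCKD
EGSEFAPDPLTIENERIFIPRVAAETDTFSAGLRSSHEFAGLFAFEESIAEYQPEITASP
NLCLRIFRKVGGEEPEGPQPVPSVDKKKDTIQTNTADKYPLISGGKYTVEYEYDHPTGPN
EFANKLNVNSLCCCALTFLAVNKVKSDEGSKIAFVINVGFGGVLIEPEVLQSGSRELWIR
SGGTEPKKATRNAPKEHNAILESHFLQVPSDIGVTPFATPQNKTACPAVQTVGF-----
>PGM2L1_rel5
EAKIQCTSVETHALFGQRMVPCVLDYGKIFGNSPSDTGEPPTGDSGHRDGILGAALDDKG
KAAITRLLVLKLSENNIGSAIFSGPEDSSVFLAVGCLPIYLMPIALLNSKDIWLITGTNP
LTKLLNWSYNGLFMIDFCRQEFTELGTECYTNMVSEGAYGGESVGEDASDSATASHNRKE
-RPQYKDTCKHGWPKSLQS-----------------------------MTIGCLYMLHRL
KDTGDQSAQKAVDIPIGGDNAGLKNYDVEGCMDSTAVCELIRDSTVQDLAAEGVNDRFNF
CVFSDVTLGTRDANMTSPVKQNGDYNENPQRKSGVKDWYINQLENLGRVSLDHSVWEGCQ
LDPDADR--PYDPETTRVVIDAIMCFFDLLCCERLSGDTVNVEENRYGVMSAGYLILCKF
EGVVKEPGPLIIEREFIFIPAGDLASRGGGAGLYYSHILHGLFAFEESIEIQGSEDSWSP
VLCCHITYRVGGEEPEDPQPLMSCIKKLDAVASNTADDTPLVHGNKSTTEYIYDQPTGPN
INANDANSITLCFVLLETLMNVAVKSIDDSWIIMNITAAFGIVLVEPENQQSLTRFLLVR
SGGTEPKKASRNAPRIENAVVESQILQVLSDIGNTYFAADIGRDQQIQVKSVRR-----
>PGM2L1_rel6
EEQVTQTNFATPLQIGQRMDPVVLDYRKVTGVLPSEKLAPPTDDSGLGAQLLGTWLDSKG
KAAFVKALNCDCSEFVKPGAIFSGPEESPVGLGNGLLPVALAPAALLNGKKIWLISGTNP
LFGQDVAVYWGLFMVDFCKRETTEADFIAYTIMFYPGASGGIPVADDLSTSLTASHNRKE
-RPCQKPECRGFAPFTAQS-----------------------------YFVLLQGMLARL
NSVGGVTMQRAIDISLTGDPSGLRVEYQEGVNDTTEQQELRWFPVVCDLHAHGVSDIFVG
GLTSDRDIGTGHANGAVSVKQPDVPNEIPGKKTGIKDWYDVQLEDLDLNSQTHPTHEGFV
LDPDADR--MYDPVLEYVVRDQVMCMAQLGEVRILLDDLCNQEANRTRNFSENAQILCKE
EGSIFAPGPLQIANAGVTQPIIDLETKAGVAMLRYSHETAGLFAFEESIFIYFSDDSLSP
NLCLRNTYTVWGAEPADPCPVPSVIKKLDTVLEATADKYPAVPGFVYTVEYIADDPTRPV
SFANDANSNTLCECTLETEMFNKVKSVDGSHDAGVSTDGTGIILIEPANQQTGTRQTLDR
SGGTEPKKESRNLPKIANAILESHVLTSNSDVRNTSTELPIGKTHTLQIGSVGI-----
>PGM2L1_rel7
VANVLLTSQATPLAIGGKWEPCILDYFPDTDPSPSQILPPPTGDSGLGAGALLGALDIKG
RDAITRALKCKLSENNIPSAIASGPAESSVALLVGQAPVANYPAAQLNSRDIWLISGTNP
LFELQVAKYNALFYNDGLRGDFTLAGTPLYTSMISIIAYGGEPKAPDASTSLTASHNRKE
-RPCYGMVCRDGLGKSLQT-----------------------------YVVDLLHMLGIR
KSVGHQSMLKPVDISQIGDSSGWRNLTQEIVNTTTAVLALTWDSVQDDVAAEGISDRIIK
GIFKDVFYGTGDASGAVPVDQNDQSNEIPQKKSGIKDWQITQKEVLQWQSWTHSEHEQGA
LDPDADR--MYDPETTYVNRDAVMCFAQRVFVKRLLPARQNIMWNGSGVWSPFYLELVFE
EGSGKFPKPDTGANAGINVPKIGLAFKTGSAGTRYSHETAALFAFEESIAIYFSDDTASP
NLLLRITYKVGGEEPEGPQPVNSVINKLDTVLRATHDKFPLTNGVKYTSEYFKDPPTMPV
INARDQNENTLCTCALHHAMFNKTISIDGYWIEMVETLGEGEVGDEPENLRSASRQLLDR
SGGTEPKKASYDLPKIAVAILESAKLLVPSDIGVRTFVLPAGKFAQPQVGSVGT-----
>PGM2L1_rel8
AAVIGQLSQATPGLRGLRMIPGSLQQGRITGQSPSDTGAPPIGASGLGATALGFALDGKW
KEAETRTEVLKVHEVVFGSLKFSGPEESSVGLGFHLCPRALYPAYLIKSKDVWLGSGTNP
LNGAQVASYNGLFMVDFFKKIITAEGAFFSTIAFSRGAYGGEPVADDPPVSLTASHNRKE
-RPCSKPDLRDGLPRSLQS-----------------------------YKVTLLIMLARA
VSICGQSMQIEVDRSQIGQPSGLRNATQTRVNDTTYQQCTIHDNVVLNLVADFVSDRFVF
CVFLDNTAGTGDANGEVPVKQNDVSVEIEFKKSGIKDWYEVQLENLKWVSLTIPTAEIFQ
WDPDADR--MYQPEATAVVRKAVMCMAYLCAVKRCLKDLCNCAANISGVGSVGALILCKA
LDSRKAPGPLGILGAGIMHPRIDLETKTLSGFLRYLVQTAGLFAFEESIEIYGSEDGASP
NLCMRVTRKVGAHEMEVPQFVNSQRKKQDTVLTGTADRSPLVPGFKTTVCVVYDDPRGPV
IFFVDAPYNDLCFCLLATTMFVKCESVDGSHIAEVFTHGISQVLIEPENQQSATKQLGDR
SGGTEPKKASWNLPKIAFYIKESHILVINSAIGNTGFPLPGGDTCLPQVGSNGI-----
>PGM2L1_rel9
LKVVQQTSQATPLYIGCRMIPCVLQYGKVGGFSPSDTLAPPTGDSGWGHGALGFKLDDKI
RALITKALVLKLSSNSIFSAIDYGPEESSVGLLNGLAPIALSPAAWLNSKDIHLISGTNP
LDGLFIISYNGLFMIDTGRREFTALGTGLYTSMISVGAYGGVPSADDGSTSLTASHNRKE
-RPLYRPEVRKGLPKYLIT-----------------------------YQVGLLIFLHKL
YSVAGQSMCGIVDISQFADPIGLRDATQEGINDTLEQQELVLDSKVQDLAAEGVSFRAVF
CVIDDNTAGTDTANGAVPNAQNDVSKEEPFVIVFRKDWYGVKLENQDKVVQTHSTHFICW
QDPDADR--MYDPELSYSVGKAVMGMAQLAEVRRLLGDLCNQELVWPGDGSPGYLRLCKI
EGSIKAPAPLTILNAGIFIPRVDIITAFGSAGLRYGHENAGWFAFEESIAIYGSADTPSP
NLCLRIKYKNGCEEPENPQQVNSVVKVLDTSLTTTHGKYPLVSGYKAVVEYVYEDPKGPV
FGAPDENSNTLCFCALHTLMFVKVKPTDGSCEAGCVWHGTGMVLIEPENGQSATRQLLDR
SGGTEPKKASRNYPDIQNKILNSHHLQLPSDIGNTSTYLPVGKTAQPQEWSKGT-----
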