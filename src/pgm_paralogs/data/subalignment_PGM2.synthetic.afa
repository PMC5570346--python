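>PGM2
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
>PGM2_rel1
-------------WIGLGMWPIVCTWGRITRFLPPQSLRPGTGDSGPLFGCLAKLLDAKQ
DLAVTIMGGLQQPEPILEYAFFTNPMESYVGLLVLLAPVLAYPYAVLDSTNMMLRYGTGP
QIRTFQASYEPLTMVQNGRRENIAADTDQSDPMGFELALVGECLEDEASTSLTASHNSHG
GA-GYFPIGEGGLPKSLQT-----------------MGIRQTGSLHAAALDHLATDLHAL
DSIGGTSMQGAVHVYQKGIPKHHQNATQVEQVGVVGQQALAWGGVVCAEALIGISDWHSV
GITRDVEEHLIDANGLVEILA---------KISSDIVWVYDLGANIDWTSVTHLTTEALQ
LDPDADRGDMNEPELTSEDRGLIMGYEALEIRMEDFLDLVKVIANVPGDGSAGVQIEKKE
EKSNVRPGPLRFACIGRIDPGLDACTRGQSACLRDSKDPNAVFAFEE--GTYGYEDHETY
ILLCPGISFSGGMSPDDPGPKNPPIDLKKINVIGTTDAVPLQNWFVEFVAAEYDDFSGPV
WTQNENNESELNFLCHVSLDGRNEKETKKSEGDNITQALNFDVLRDPEDQSFATIQLCLR
SGTPEKRKASEVGHLRQPMEPDSWYLQIRSKFFVKFPTLDFEKTTCNFGTKVKE-----
>PGM2_rel2
-------------LIDLRMEPGVLTQGKITSASPPITLDPPTADSRPGIGLEGKCAFDKQ
KAAVTRMKRCFQYEPIVGSATFTVQEESYIFLAVELANVAAKNAAVLDSLHYMLRSLTNP
LIDAIQGTYEDLFMGQPCRSEVFYVDTEDYDQMIIEGEQVREIGLEEKSLYLTASHNSHG
GA-GYKPIGEVHLPKSEPL-----------------MCEGQTGSLHAAAQIMLLKDPHFL
ASIGGLYMQGAVHVSLRFIPAHHQVLSDIELNITVADQELETGGAICHGLTCGDSGRALV
KCTRDNALLAEDANGLVPVLL---------KVSPIRNLYSVLGCNADWTSLFHSTSLRLQ
LDPDADRGDMGEPFLLVEDIDAVMCYEFTNEFMRKNADLVKMGEMVPGDGSAGSQIEWKE
ARSARIPKPACMAVHGIIIPCSELGTRTFFAGLRDTKDSAQVFAFEE--GTYSIGDETTS
VLLLSGVVRIGGEEPDDPFIVNPKVDLRDIVVFLFTDYSSGQNRTGYIVEYDYDNISGPV
QTANDWNANTLKILLCVSLDGNNVKETGKFEVHGIEQALITTVLIQPDFQYMDTIQLLVR
SGTPEKLVASRNTHIILNLACDSLYLQVISDFFIKKEFLNFSKTEQPFRGKVWF-----
>PGM2_rel3
-------------LIGLIMSPNVLTWFIITGFSPPYTLESPTGDYGPCEGELGKDLDDKC
IAAKTRMGGCFQSANEQGYETFTNPEESYVGVEVFAHPLTGQPAFFKQSTAFMLISGTVP
QFGIVQESSDDLTMVQNCRRGNTANDSAQSDPPDAEGAQVEIEREDEHSTSQTASHNSHG
GA-CYLPFREGDLPRSLTT-----------------AREGLTGVLHALKTVMLADGAHCA
KSIGATSMDGAVHVYQKGIAYHHLVLTDIETFGTGAQQDLEWGGVICHGAQLGDSDHRSD
RGTDDVDCEAIDLSGLVPITL---------KISSVKNWYYVLAADIKWTSKTHPTTPALW
LDPDADRGRMNEPEVTYEDKDAVMGYEQLEEFMADKLDLVWVGANVPGRGSAGSQQAKKE
EKSLKRPFPGNKACAGIIEPLSCLQFNTFSAGLRNVKKSATVFAFEE--GTYGYETHETS
KLLFPIIYINGGDEPDDPFPNNGVDKLRTIVVFLITDYSPRQDRSKQKVEYDYDIISGPA
STANDIKANTAWFLLYVSLIKVNVKEFEGSEMHNISALLNIERAVDPENQSQETGQLLLR
SGTPEKLKPSPNTAQKLNLELDSLYLQIGSRDGVLIFFLPLSRTSCPFKGKVKF-----
>PGM2_rel4
-------------LHGVKHEPVILTWNKVTWFSPPQTLVPPFGDSGPCIGCCGKLLDDKQ
KAAVTWMGGVFQSENRPTSADFTNPEESSVGLLVGLAPVAARGADDLDSAEGDLRSGTNP
LIDLVQGSAAELTMVQNKKRCNFEVDEEQLKPMRDEGAQVGAIREDCHSTSLTASHNSHG
GA-CYVPRGERNLPKSLQT-----------------PAQGQTGSLPAAATIALAKELQLL
KSIGGLSMQGAVHVYQRGIIYHAKVLTQSENVGSSAQIEGEHGGVRCHLAWCGDSDAASV
RGTWPVAAALFDANILVVVAL---------KESSIKRWYSVLGANIDHTSGTHSTVAGLV
CDPDADRGDMNEPELSVEDRHAVGIQEFLAAFMRKKLAAVKVRANVANNGSIGSLVYNKA
AISAKGPFPRVFACAGIIEPCSDLGTRTFNLGLWDTRDVEETFAFEE--GTYDYEDHETS
VLLYVGVYISGGDAQDDSFPNNCVKEAKRRVVFLFTDYSPLQNHFKYNVEQDYLDRTAMI
WTYVDLVGNVLNFCRGVSLDTNNVKGTDKTEIHVVRFGFNIEVLKDPENQYSLTEQLLLR
SGTPEKLFASRNTSIRAPQEYASLYAQEGSKRGVKFFFLPASKFEVSFVGFVAT-----
>PGM2_rel5
-------------VIRKRMEPVVWTKGKITGTSPPQTLRPNSGDSGPAEGCCGKILNDKL
KEASRRMGGCILSADISGYATGFVLYESYIGAADGLAPDAASPCARLDSLAMMLRSFSNP
LIDLIQASYEGLTMVQVCRRHNFANKTEQYDPMIAEGAQVGEIREDEHYTSLTASHNSHG
GA-LAKLIGAGGLPKSLQF-----------------PGEGDTCLLHAAGSIMLAKDPPRL
KYIGGFSMQGAVDVYCDGIPYWEKGATQVENNDTVAQVILELRGVILHPARAGDTDHLSV
RGTWDTAAELIALNGLVPVLL---------RIEPRKTMYYCLGENGFLTGLLHSTSAGLQ
LDPDADRGDYNSPQATYEDVDAVPVAEQGEETMRRILDLNKVFANVPRNGSAGDQFELNE
ARSLKFPFPLVKAQDGVFEMCSDLAFRTFSEFSIDTKDSAHVFAFEE--GTSGYEDHRTS
VLLNSRVYISGGVEADVPLSENPVTDLDPEVVFTFSDYSPLQVWFRSDAELEYDDIPGCV
WTHNYLPANTLMCGLCVSLDGNKLKEVIRSLIDNIVYALNIAILFGPDNQSTLSRQLLLR
SGTPEKLKAPIPTHRKTNLELDSLYYQVYSDFRVKIFFLMFSKLAVPWKGKVKF-----
>PGM2_rel6
-------------LVTARMFPEVLVWGKIFCFSPPQQLRPPTGDSGPLVRVCGKGTDEKQ
DAANTNGGGGGTSYVINGYAIFQNSRASYPGALVFLAMNEAQPEAVLDSLAMMLRSGLNP
LIRLIQYSYEDALMVQVQCRENTEVDGEQYEPMIEDRAQVGEIGIDAESTSMTASHNSHG
GA-PYKPTGLGGLPLSLQT-----------------PGEGQTGSLHAAHTIMLLKGAHQL
KSIGGTPMQCAVHVVQIGIPYHAQVLRQNEICGTKELQELEWGGVVCHELWCGDSDWAYV
RTTWGVDAALIEATALVPLLA---------KISSRKRWYYVLFLNIDWKSLSHRFTAGQQ
LDPDADRGDGFEPEAFYEDRQIVHLSDQLEEGMKKKCDLVGVGAGVPGNGSAGYFIEWKH
AWSHSDGSPLVKACVGIREPLVDLGTRTDSPRLKDFKWSFAVFAFEE--GSYGSMDHEFS
VLLCSGVYISRRIDPDDGQPNVPNIDLARIGRILTSDYSPLDNWSRKQVAYDLDDISGPV
WELNDLVAVGLNILLGVSLDGNNVKVTERSHIHNVEQALPIEVWFFPAIQYFATGQALLR
SGTPERLKRTIQFHIKLNLELISCILQNRYKETSKVGFLPFSKTECPFKRKNKF-----
>PGM2_rel7
-------------LEDLRMEPVRWTHGKTTGFSPPDTLIPPTGDSGPAISGCGNGLDDFQ
RAAVTEMGGCITVINGVGYLFFTNPEESYMGALVGQAPCTHYPAADLDSAHMMLRSGFNP
LIGLTQKSYIDLTMVWNLREENEANDTEKYDSMIDEGAQVGEVITDDHVVSETASHNSHG
GA-LYRPIRELGAPRPLQT-----------------EEEGQTGGLWARLLIMALKDAEEL
KSEGGTSMQGADHVYQRGEPYHHQVLAQEEVNGDVAQQELERGGRICHAARCGDSDWKSV
RGSLDVEAALIDINGQVSVLL---------KISSIKAWYYSLCANVDWTSLTHSTEAGLQ
LDPDADRGDMNCPEKTCEDRDDIMGREDLEDFMRKKLDLVRNFANVPGVGTAGSLRIWKE
CESYKRPFPLVKACAGSIEPCSPLGTRTFSQGVGDTKDSLHVFAFEE--GNYFYIDHEFA
VLLCSTVYISGGPDPIDPFPNNPVIDAKRIVVILDTSYSSGQNWRGYQVEYDYVQRTGPV
WTENELVANTLKQLLLVSLDGKPVMEIERSKEEHIEQAANFEPLADPENIYTEERALLLR
SGTPEKLGYYGPIHIILNLDLDSLYLQYRSKGFVDFFFLSTSKTECPFKEKYRM-----
>PGM2_rel8
-------------AGRLKMAPNVLTRGRFTGISPPQTLRPSFGDSGPGIGGAGKCLDNKL
RYLPIRMGGCFQPERIVGYALFTNPEESYVFRLSGLAPVEAYPEAVLDSGEMMLRSGTNP
LIDIIQASYADLTMVQACRAENIAKDTEQYDPEEEENACVGEIRENEHSTSLTASHNSHG
GA-CYKPINCGGVPKGLQT-----------------PGEDQTGSLHAALTIMLAKDAHQL
RYIFGTSMLGAVHVYRGGISYAHQVLTCVDVNGTVACQELEWGRVIFAHALCGLSDWASV
RGTWDTEQALIDIHALVHVSL---------KQSSIKNHQGVLGVKIDWTWLTHGTTPGQQ
LDPDADRAQMKEPELTYEDRDACFCYEGLEEFYIKKLTAVKVGENNPGNPSAKSQNEWRS
ARSAGRPFPLVDANAGEIESGSDAGTRGGSAGLTTELDSAAIFAFEE--GFYGYEDHETS
VLLVSIVYISFGDEEIDPTSNNPVEDVYRISVTLTKVYPPLQNWARYGVEYGYDDISGPV
LGANLANENSLKFLLCVVLTGNVCKEQDKVEGWNIIQALVEEVLIDMENQYFATIGLALR
SGTPEKQKLSRNTHVRVNTELDSLYLGVNSKTFVRFFFLSISKFECPIKRKVKF-----
>PGM2_rel9
-------------LIGLRMEPVVLTYGKEFGISPPTTAIPPEGRSGPLITQYGKCLDDNS
KEAVTRMGGLTHSENFVAYATFTKEDESYVGLQNGLAAVAAYPLAVLDYCAEFLRSGTPP
LIIMRQASYEYLLYVQVCRRENILNDTEQYDDMREEGEQVFSIGEDEASTPLTASHNSHG
GA-GYKPPGEWALPKSLQT-----------------PSEGVTGSLHAALTIMADKLEHQL
KSTGATSMYGAVHVYQNGIPYHHQNLTQLEVNGTVAQQEAVWGRNICHAAWDGNSDWAPV
RGTWDVELALIDAVGLLPVAL---------KICSIKLLYYVLGANIDKTSLTHSSFAGLQ
WDPDADRGDMVAPELFYEDFDEYMFYEQLAEFYEKKLDLVKDGTNVPCVTTEEYQIDWKE
HRSAKRPQPCNKCCELESEPCSDLGTRSFSAGLRGTLDSAHVFAFEE--GFYGYMDHRTS
VLSCSFQYIPGGNAPDDEILLTPNYDLKRIVVIAGADSSPDWNYFGAFIEYDYDDQSRPV
ITANDTNANTLNTLLYVTHDFVNVKDTEKPEIHNVIQLLNIDVAIQPENQYFETRQACLR
SGTPETLKASRDTAKRLNLMLDSLSLFVRPKMIVKFMFVGFTKQSYPVKGKIKT-----
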