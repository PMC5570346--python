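>PGM5
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
>PGM5_rel1
-------------------------------------------------------TDDKD
SMELPADIILDQTYNNVGYLRISGEIEPSVDQHIGSFNAHASPGSSLVSKSEDVRGRGNC
FYTCFALQSTEYDMNLQSKIEIVTVAQAGIMSREHILAYNLEPKAMIHSFSSTASHN--P
GGPGFASARSECLPKVLQSLGGAVTGFADELPANYVADRKHSSSGHHSATVQQALLLEQL
RGVLERSMQHNNHGSLKLIPYTYRFITLVSVNENDAGLICCNESINQTYCMATGAPIHNG
ASNLLVIGVERKAEGSVNRVD------------SKKMGAYVAAAQGEIASTRASTFVEKL
LDGDGDR------------------MHHLLEVARALLVLVRTALNKYGKLRFVYQAMGVV
TGSRRHVILWVGLEAPSVCPFSDWETDQGPAIFKGDSLAHLTESGEESFSVYTSVAAKFP
SAWLQICAMPRGIFIEIAAVRISVKLLEGKEFTR-----PQVNWIAYTDARFDIEASIPS
FDLNRLKQFFLNMWETHTLKARKVKPEARQLGLSVLVAQDRAGLRTFVNLEFAFKEQSDR
GSGTSGARVGIRKHRNQQLIEQEGQLTSRITLSLTRGFACALRTRQPAIRILDGRLRGI
>PGM5_rel2
-------------------------------------------------------TQDKD
SNELTHDIIQDQSIKNVFPRRISALFAPPRDQLVGSLPIHHSSQESKNYDAEGIRTETNV
QLLLIAAFSNYSVMALQSKNATCENHQETIMSREHQLAYVLEPKAMGASGSFTASHN--P
GGPCVLFAKSELQMKVQQPLGGAIQGKEDECPNGYTNDRKAASSGLHTLTEQQAKCYAVL
KVVLAKSMQAGNPMYQFLLPYTYKIIFQVSINEPDANLALANESIVQTYAMQLGKPLQPI
ASNCHVVGAQRDLAGSSNKVT------------MSRMINYNGAICETWTSTKASTEGEYR
LDGDGDR------------------YWRLLEVAKEALLYVKSKLNKSGKLRISYQAIAKV
TATRKHSFKRRLLNMPSICPGSDKETDLRPLRLKGRSDDHLDEYGEESFSLYTSVAAKTP
SAQCDIVDKSHGEIIEYHAPRISVRGAFFKDVLR-----PQFNKQAYWIFRFDNAATIPS
TDVNALVLIFLLMLTWDTLRLRKEKPTARVYTGYTQFAQEIRALRIFNNLEFAFWELSDR
GSGTSGARVGIRKDRRLDCEILEGQCSPIFFCSGVRGDNDTLGTADPAEGRLTIKLRGI
>PGM5_rel3
-------------------------------------------------------LDIND
SMVLTADIDQEQFEDNVRYARRRGPIEPPPDEHEGPAAVAAGPGESTASKAEGVRDITVR
FALVREATSNEYVIKCQSRDETKANHQEGITSLGCVLARVLAPKGMELPGSKTASHN--P
GGPGICSAGSELLPKVLESLGGAITGFHDILPLNYVADIKANPSGHATETVQVAKLYDQL
KVVLAGSMQHNIPLSCKLLPYTYKIITQKSINHPEAGLKCHNESIVQTYAMASRAPWHTI
YSILAVVGAQRDAEGSVVFND------------SRWMIHYVEAIGCIAISTVRSTFFENR
LDGDGDR------------------YHQLAAVAKAALDLVKQHWNKSGKLRDVYKAFATV
TGSRKHSIKRVGLVLPSIVPISDWATDQDPLRLKGTSDDHLDESGEESFSCYTSVAHKFP
RAFLIINKYSRGEIVIFLAGKITEIALIRKEQSR-----PAVNYDAYTEERFIIEASESY
TDYIDLVLFGLDMLSTWGLRLKKQKPTLRVYNLQVLVAQEFGHLITFVRGDIEILECDDR
GSGTSGARVGIRKDRFLDCIIYEFQLTGAIFLSGCRGTNPFLRTLQAAVGFADFKLRGI
>PGM5_rel4
-------------------------------------------------------TDKKD
SMIATAEIILEQYANNVGYAAIVGPKCPPQDPAIGSCPVHCSPGESLNSKAECVAEITRV
FALGRMATSNESIMFLQSKILTSANEQEGVMSREHNLAYILENKLMEASTGITASHN--P
GGVCILSAGSILQPRVLLPAGCKRTGFAAEVPLNYCVDRKESSTGHHTHSVQQSKLIEDL
MNVLAGSMQENNPGSMKAAPYTYKVITQVSVCIPDAGLAQAYESIVQTYPAATGHPLHPI
GSNLLVVGRGEDAEGSVCDVE------------SRRMIAYIFAEICIHTSTVHSTFGDKL
LDGDGDR------------------MAQQLEVFKAAAVLDKIHLAKYGKCDGIYQAFHVK
TGSKRHSIKWVGRKAPSICPFTDWETDTGPLRLKGRPDDEADESGEESFSVATSIAAKFP
LAQLDINDDPKGEIIEFAEPKFSVRDLDNRDQTR-----PENNIFAYTVERFDTEASEPG
TDYNDLVQTFLRMQGTRFAVLRNSKMTAGVYGLYVQVAQEIAALRTTVNLEVANLELSDR
GSGTSGARVGIRKDRRLDLFEQDCQLVYKIVLYGVRFKLPTLATAFYAIERLDFKLKRE
>PGM5_rel5
-------------------------------------------------------TGDKD
SMALMADIHQDQSENNNGRAGLTDPVLPPVNQHWARCPVHAPPGESLNSKHEGVRDITNV
FALQQEATSNESVMTLQSKQETGAKHQAGIFSRIHDLEEVLGPDLMEATFPFTASHN--P
GGPIFLSIDSELLPKNWQSLGFAITGKALVVPCNYVPDLRASSSLAHTATVQQAKLREQL
KNVLPGSMDHVPPGSQKLGPASYKIITQNSESEPDAGAALAIESEIQTYEMGTFAPKHPF
ASNELVVGAQFDQSGSVVEID------------SRRMIEYVFLECCFWTSTIATSFFEDS
LDGDGDR------------------YITLLEIAKEALVLVKQYLPKSGKIRGMYKAKHVF
TGSRAHSIKWQGLILPSVCMFSDWDTKFGPLRCKGGSDSHLDEVGEESFSVYTSLYATFP
SAQLDIIDYPVGEIIEIHAPRISVKTAIRLDNTR-----PQVNRFEYSREQFDIEYSEPS
VGYNRLVLFFLNMTALAFLRARCVKPTFRCSYHYVQQAQEILALIKIFNLEIAFREVTDR
GSGTSGARVGIRKERRLSYNETEEQLFSIIFTLGCRGFNPFLGEDGPAIGVLDMKLKAI
>PGM5_rel6
-------------------------------------------------------SDDKD
YYELLGDIIQDQSENAVGHTWVSGPDEPLIQQHLGTCPVEGSPKESADSKLEAIIDITNV
GALLIHATSNESVMQLQSKGETVADHQEGIMSREHVLAYSLEPRAMEASNPKTASHN--P
GGPQVLSLGIEVLVKVLQSLGGAAAGFADELPCNYVEDRKASSLGHATALHQQAKLYAQL
KNVLAISMQHRWPLSLKLLPYTYKIIFQESIFEPDFGLALAGESRVQTYAMATGHPWHPT
ASNLLVVGAQREASISVNIQD------------SRWMIEYVFAECCPHTSAWAVTFFIAR
LDGDGDR------------------QHQLLEVAKEAAIAAKTHLNFRGKLRGEYQAEAVV
TPSIKHYVKWVGAVASSGCPFNDSETEKGPLRLKIATEVATGESGEESFSKYTVVRAKGD
SAQLDIKDYPKGAIVEFAAPVISVFAGGRKGVTR-----PQRNKMYYTRENFDEDFSAAI
TDYNDLTLFSLNMLCSHTLGLRKVFPTLRNYFCSLLIAQMIAALLFFVSLHIHTWDSSDR
GSGTSGARVGIRKDIILDLSFQSGCLISRFFLSGIRLFNPTLGSAAPAIGELDFKLRRI
>PGM5_rel7
-------------------------------------------------------TDGKD
SMELTADRIADQSAVNVAYLIIIGPTEPVIDVHIGECPIHAPDNESLNSKAEGVGDITNV
FKDAVAATSRVAVNTQQSKIETYNNHQEGRFSKEHVLAYVAIPKAMIASFYKTASHN--P
GGPCICSAGSILLPKVLQSLGAEITGGADECPCVYVEDRLAISTGPHTATVQQAKLSIQL
RNVLAGSMAANKPGSCSCQPYTTKIRTQVSYNEPLAGLALTNISKNLTQAEFSKKPWHPF
ISNLLIVGAQKDREGSVNVFD------------VRRMICYVIAECCIETSTRASTFFEKL
LDGDGDR------------------YHCALAVAKEELVLRIQHLNKSGKLRGISQAFAVN
TGSIKTPKKWVGLSLPSNCPFYVWETDQGELRLDAASDDHLDSSGEESFSVYTSVAEKFP
YAQLIVVDYPRGEIVDFAAPRISVIALIRKDQTR-----PQKNRFAYTIERFDFELSEPS
TDYNDLCLFFLVPLLAHTLRLVKIKPGARVYNCLVQRAQEIAALKTFVNLEIAFKAASQR
GSGTSGARVGIRKDRKFDLFVQEGQVTSTRFCSGVTGFVDFLGKAQPHIGIGDFKLRGI
>PGM5_rel8
-------------------------------------------------------TDDRD
SMDLAPAIIQRQSGNNVGYHKISGPIEPPQDQHVGTNPVAASPGESLNSKAEGCWLITNV
IALVIGATSVEYVGFYYSNDETVAVHDEGIMSKEHNLAYTLEPKAMEASMDRTASHN--P
GGPGILSEFSELLPKVLQSLGNAVSGFHDECSCTMQEDRRESSSGHHTATVQQADLYEQA
KNVLAGVMQHNFSGSKKLLKYLDRIISCVSIVEPDACAHLANESIVQLYKPAIDLPWHPI
ASVLCAVGALRKLFGSTNITV------------SVRFFAYFFAECCIITSSGAVTGFARL
LDGDGDR------------------AHLLLEIADEELVQNKFHLNKSGKLRGVLQAFRVV
FGYAKHSEKHVTGIHPSSKPFSIWITRLKPLRAKGRPDDHLIESGEESFSVSTFIAAKFP
SAQWDIFDYPRGEIIELELPRISVRDLSWKEQTR-----PQNNRFHYLRERTDISLSEPS
TKYNQLVLFFLVMLKTHTLRLIKVTSTLWDYFLYVQVAQTIHLLKTFPNLDIAMWEQSDR
GSGTSGARVGIRKDRRLDLIIQEGQQTSRIFLSGVRGLNPTLRSALPASGILKFRLIGV
>PGM5_rel9
-------------------------------------------------------TTDKD
SMEQTADIVQQQSANNVGRLRISGPVEPMVDQHRGSGPVHATPGESQNSKAEGQRITLNI
FALCIAKTSNAYVMFLQSVEETVEKHQEGIMSREHVLAIKLEPKAMELSGSTTASHN--P
GGQCILRAGSMLLPKVAQSCGLANTCFADECPCWRVMDRLASSSAHHFGTNQQALLYEQL
KNCWEGTFQHNNSGSCKLLDYFYKINTFVSENAPDLMWHLESISDVDTYGMATGADRHEI
ASFLLVVAEQLDEEGSINDSD------------SGRMICLVMAEQCIWTYTGASDCFQKL
LDGDGDR------------------YHQLLEVEKEPLVLVKSHLMKSGIAKGVYDHFARV
TASRKHSGLNIGGILPSVQPFSDWEVDQGPLRLRFKSDDHADASGEESFSVYTLVKAKFP
SRQLDVVDYPDGAKEEFALPRISIRALIRKDVQR-----PQVFRFAYIIERFDREASAPS
RGYNDLVLQWLIYLATHELRLRKVKPTAHVYFLYVDQAVEILALKTMVNLQILFQERSDR
GSGTSGARVGIRKNRNLDCIFQEGQWTSRIFASNVRGGKPFLGEAQPAIGILDTALKII
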