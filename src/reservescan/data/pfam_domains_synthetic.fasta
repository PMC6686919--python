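>PF00106
LFMIRFQPSGWMGRDNMEYGNRKRKKYARDKPGECNMDKWFVWQLSMCPPLLHFESIVNP
QWGEWGMYDLICLNSQMDYRFRRHGPWTTDCIPHNTSFNV
>PF00108
LQVSQQDDHRFRWQVCTHFRLKKRYWVSCWLFIQSDPVAKNHQGPSFIRKLWDVFIDYSL
SAVSTPLVAAWWLPGWMGPHKYADFFIFHWCEYHCLPIQD
>PF00171
AANGHCQFEQKNLDWMHRKSAPVYGFHSCTGHDIYAELNNFHNIHLHIAGFLVTEDWAWP
NDVRTDMWQPAQEIYFKSDSDITENFTEYWPRMVHNMTET
>PF00465
HSGFALQRNYGIWALPQNGDWTNVACSNDKARYTDWALAVTTPDQLHSLDWPVFMFNCAQ
FSTMPCIMTMHQYRCENYLLGYDEKCQNNKMFDWCYVNFG
>PF00483
PCPMWTLEECADMGYEFCMEGSHTVLGGHTVATINFNQWIWCMRCHAINHIFWTNATEWE
WAWLFQYHVADRCSMRLDMVIAPPKMTRMPHTSMPHMPAN
>PF00534
VRGLKQFWYFDLGYVCYKGQWQSNLVQVEFAMGVSTSDHGFRMSDGGSAHECDKEFNELW
AAGMSQGWFNNTGECEKIDGLAWQGESAVAWFEPLPYKRR
>PF00561
SCPRIGQMTFPMEAQRLEESTNCACIRGISSENMFWTRPFPYADNISEQMMIFYAWTGQN
QEPNSPHWAMPKYSPEIMERVCVIGMAGYHDHKAFWTSEV
>PF00698
IKWFQPMSQPIFNVIHHAEDCHIFQHSTNGWKFIVLGHTPTFKNEPANSCEIMHATILLD
YLCSFYWITEHHMRVWYAYPYCMGLPTLPWEQTCSTYDSP
>PF01575
FEPTQQNIYRNRFCILPHLFEAMTYGNNLSPGLCGVIGPNTAELEFSLFTAPCPCTATEM
INWIKHWQPGKRHKQWRLDYAFCVKRFRKTSGLEWTIAFP
>PF02450
VGHRSENTHHYNSVCLQYNFQSKGVRMYWYDTQCYHPRILPNHVKYTMKPLHPEFYQTGY
TTTIRDHLIVFWDKYARQQAWRDKYIFTDGPEWWCHLRDT
>PF02541
GYNRRTNRDCVGVLECGASQWREVQAGCSYWQLPYYWEPIFVWFYTHAMGPDVEAFNRQS
YGACMWGHCQPSYTCSAKLHHTPMEHEFRHYIQTSTGCML
>PF02550
PRLNFEEMWLRTMAEWKLAWQSPEDHLLKWEDDAFMREMWNQVWWQVGEYLNYHYTWCFE
NWQICYAQETEKMVGENMCKRSDKHRYSRTRDSYVGVTEM
>PF02803
FLMLLESNKVKPETWAKYDQICEPRETMMNQHQNTICWVRVMSNPNMHMAAEHMHRRWQG
IEAGDYRRSLKRTVETLGAIDLTTTNFMCEMSDCWNVICI
>PF03007
RRRYNAIFECCIWCIQVRGDYPIKLCQCVWDMYCMDIDWYGANRFVAQIRLCIGQCGFYR
DSFWRHDSNYDARQILFWVKINWTPVKGGHEDWYYYKCRE
>PF03976
FEPGMNGVNMGHPMLNSMKLSVHCWLGCYPEIGTLSGAWLVPKYNKDWSEEIWRLKDCKL
RLFSREIQNSRYYVGGAHVLNEMCGCMLQLNYKKWIDPHR
>PF06974
EWVLGGYFWFTWKHWDAKTKQTLNYGKPWTPFFACLHWNEPMCCECMDELRPMHQHFSQC
LHLMTWQPNHETMEWVGCFPECAKYLVDRKCDSHSERQHN
>PF07167
SHSFSPKCYTSLISTPMGDLWWRQNEQNFSPSENCCMTPFEYSTNDPIMQVTFRPNASNE
KYCSGHTAINYTMCHRLKDRLQIFGPECIKIPTSDYIDPK
>PF08323
IMYHAIPFDPKLTSIIPQKYQYIDISVDCSPCEQWTHKYLSEFYCMNKFGSRVSEYSSQQ
EFRTWFRAVWWKLIWPHPAIGCYSAHKFMVKQARLVKRGE
>PF13336
PNCVSWYACHKNIGWDYHWCLACFEYCNDHWLLCMIYTFQNATTGQYHFKHGSHAHVFFI
RGIPGVFEPPDWPLYKFYPICSLCKGESAEEGTKFQMQFF
>PF13439
KMKVMFKYEDNSRSKSRWIQQRLWHAGMSIFEPFFRQKWRNTCFRYSNAIRVTTCESFCR
WQDGCPRRCPGFMGWTLMIMCQSAHRLHNYAEPWEPIVEK
>PF13561
WGWIERPPQHNYHDHDCLRGPWMAQEAPTKHDCWCKTYCICPQYGDQVLAGLHYTMWMIW
EQPKPLPRAHEGHNDAFGMCHWQMQKDATKQIIKVEKGMN
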