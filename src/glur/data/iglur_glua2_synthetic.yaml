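# Synthetic stand-in for the mature rat GluA2 reference (862 aa).
# Diagnostic residues are planted at the canonical mature-numbering
# positions; the inter-site background is random and carries no
# biological information. Override with a real sequence if available.
name: iGluR-GluA2-mature
description: synthetic GluA2-like mature reference with planted diagnostic sites
sites:
  "423": 423
  "485": 485
  "586": 586
  "590": 590
  "653": 653
  "655": 655
  "704": 704
  "705": 705
motif:
  label: SYTANLAAF
  start: 600
sequence: |
  KQAASYKPLYSATAPDTLEGARFKKGVVFMFGNPLEITYGLEKEGWDKRTSCTAENISCA
  GDRLEFDVGRKYHVIGKVVIPILSGPPYRPYVATVVNVTSICSYQLHYAPKAPAPLYATA
  EHVLQCTDRQLLSLQGSKVGLKTNGYASGSAGRMQFVRTAGHIVSEQTTLEVEDTSMVYP
  TQNFPNGYLLDLLRVLASVLEDFDLKVAIPDGAPRGTIYSYRAATKINFEPILSRLDSIV
  DVSISKMYATGEVSIGTRFSSESDGGLRGAPTNFSVTGVVLPYITFESLRGAIHGLRYFS
  WLAPLSLSVENGPHLRPQDTLIWRFEDFGEVDLANTSLDLAPPKKACLGVYNLFNEPWEC
  SLIQAALDVRIGCPKPRELGADVNTSGISFTPFYSDPRGGDVRAEVQSNLVPVLVTSTKG
  LDENLLFPRKGKFLPLIQCFFDVFLTIIQNPTFGLLVGNTWADKSKDRLSDALDASSGEQ
  GLLGRFLGKKEELKKGLVHTRTVQAIDVWVKLTMQYHSLDELNAHSKEPIVSSQNDHLDS
  TELLIAAVFLFAFIIVLAAVLFFNRALNSAGIDGDQYGGKMMRLPQLNRDYIWIPIFETS
  YTANLAAFADGVAVVVALAVILLVAILVFMVVADCPLIDPRQSITKSDEGIIGNTTAAEG
  VASINGGCEGVIVAAAMDLSECPINRPTWLNDITMQPHVHTAPNEDYDLKTISLVPYVSR
  RKQGNSTNLGSIPLVGVGDSQLKDAVSRTQQSPTNPIEPTENVYQSRYSDEKGPKDKARN
  GAYCQGVEHMLFFVILLMVALLVLLVILIMDIVAGEGTHTLGQSKDNRYGSWDADSALDS
  ILEIASYPITAMSETAKEKQDK
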